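import numpy as np
import pytest

from methdual import calling, simulate
from methdual.genome import window_frame


@pytest.fixture(scope="session")
def toy_genome():
    return simulate.generate_genome(seed=7)


@pytest.fixture(scope="session")
def planted(toy_genome):
    latent, truth = simulate.plant_methylomes(toy_genome, seed=8)
    return latent, truth


@pytest.fixture(scope="session")
def tracks(toy_genome, planted):
    latent, _ = planted
    return simulate.simulate_counts(latent, toy_genome, seed=9)


@pytest.fixture(scope="session")
def call_sets(tracks):
    ne = tracks["NE"]
    eac = [calling.call_pairwise_dmrs(ne, tracks[s]) for s in simulate.EAC_SAMPLES]
    upsc = [calling.call_pairwise_dmrs(ne, tracks[s]) for s in simulate.UPSC_SAMPLES]
    return eac, upsc


@pytest.fixture(scope="session")
def consensus(toy_genome, call_sets):
    eac_calls, upsc_calls = call_sets
    eac = calling.consensus_dmrs(eac_calls, "EAC", toy_genome.frame)
    upsc = calling.consensus_dmrs(upsc_calls, "UPSC", toy_genome.frame)
    return eac, upsc


@pytest.fixture
def small_frame():
    return window_frame({"chrA": 10_000}, 500)


def make_track(frame, sample_id="s", medip=None, mre=None, cpg=None, mre_sites=None,
               cnv=None):
    n = len(frame)
    return calling.WindowedCountTrack(
        sample_id=sample_id, frame=frame,
        medip=np.asarray(medip if medip is not None else np.full(n, 10)),
        mre=np.asarray(mre if mre is not None else np.full(n, 10)),
        cpg_count=np.asarray(cpg if cpg is not None else np.full(n, 5)),
        mre_site_count=np.asarray(mre_sites if mre_sites is not None else np.full(n, 2)),
        cnv_factor=cnv,
    )
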