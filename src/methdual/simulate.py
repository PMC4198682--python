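"""Synthetic toy genome, latent methylomes and dual-assay count tracks.

The generator emulates the study design the pipeline analyzes: one pooled
normal endometrium methylome (NE), three tumors of each of two cancer
types (EAC1-3, UPSC1-3), and an embryonic-stem-cell reference (H1), all
laid out on a small two-chromosome genome (default 2 x 2 Mb, one
chromosome flagged X-like).

CpGs follow a two-rate clustered process: a high homogeneous rate inside
CpG islands, and a clustered background component elsewhere (cluster
centers with locally Gaussian-scattered CpGs), mirroring the fact that
genomic CpGs are aggregated rather than uniformly scattered. A fixed
random quarter of CpGs are flagged as MRE sites (a stand-in for
methylation-sensitive restriction-enzyme recognition sites).

Baseline normal methylation is low (~0.1) in CGI/promoter windows and
high (~0.8) elsewhere. Planted differential windows (hyper at CpG
islands, hypo at CpG-dense background windows) come in three focal
classes - EAC-only, UPSC-only, and shared - plus one contiguous
hypomethylated block covering half of the X-like chromosome in UPSC only.
Planted windows are drawn from CpG-dense windows because both assays are
CpG-conditional: a differential call is only defined where CpGs exist,
and real DMRs concentrate at CpG-dense regulatory loci.

Counts are Poisson: MeDIP rate is proportional to methylation times CpG
density, MRE rate to (1 - methylation) times MRE-site density, each scaled
by sequencing depth and the window's copy-number factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import WindowedCountTrack
from .cohort import BetaCohort
from .genome import (
    ChromHMMSegment,
    GenomicInterval,
    TEAnnotation,
    WindowFrame,
    intervals_to_window_indices,
    window_frame,
)

__all__ = [
    "GenomeConfig",
    "DMRDesign",
    "DepthConfig",
    "CohortConfig",
    "ToyGenome",
    "LatentMethylome",
    "PlantedDMR",
    "TruthSet",
    "generate_genome",
    "plant_methylomes",
    "simulate_counts",
    "simulate_probe_cohort",
    "simulate_chromhmm",
    "default_state_map",
]

TUMOR_SAMPLES = ("EAC1", "EAC2", "EAC3", "UPSC1", "UPSC2", "UPSC3")
EAC_SAMPLES = TUMOR_SAMPLES[:3]
UPSC_SAMPLES = TUMOR_SAMPLES[3:]


@dataclass
class GenomeConfig:
    chrom_names: tuple[str, ...] = ("chr1", "chrX")
    chrom_length: int = 2_000_000
    x_like: str = "chrX"
    window: int = 500
    n_cgis_per_chrom: int = 60
    cgi_length_range: tuple[int, int] = (600, 1500)
    cgi_cpg_rate: float = 0.06          # per bp, homogeneous inside CGIs
    bg_cluster_rate: float = 0.0006     # cluster centers per bp
    bg_cluster_size_mean: float = 18.0  # CpGs per background cluster
    bg_cluster_sd: float = 150.0        # spatial scatter of a cluster (bp)
    mre_fraction: float = 0.25
    n_genes_per_chrom: int = 30
    gene_length_range: tuple[int, int] = (4_000, 20_000)
    n_mirna_tss_per_chrom: int = 5
    n_lncrna_tss_per_chrom: int = 5
    te_subfamilies: dict[str, tuple[str, str, int]] = field(default_factory=lambda: {
        # subfamily -> (family, class, copies per chromosome)
        "LTR6A": ("ERV1", "LTR", 15),
        "MER52A": ("ERV1", "LTR", 15),
        "AluYt": ("Alu", "SINE", 25),
        "L1Mt": ("L1", "LINE", 20),
    })
    te_length_range: tuple[int, int] = (300, 600)
    enhancer_te_subfamilies: tuple[str, ...] = ("MER52A", "LTR6A")


@dataclass
class ToyGenome:
    config: GenomeConfig
    chrom_sizes: dict[str, int]
    frame: WindowFrame
    cpg_positions: dict[str, np.ndarray]
    mre_site_positions: dict[str, np.ndarray]
    cgis: list[GenomicInterval]
    promoters: list[GenomicInterval]
    gene_bodies: list[GenomicInterval]
    exons: list[GenomicInterval]
    tss_lists: dict[str, list[tuple[str, int]]]
    te_catalog: list[TEAnnotation]
    _window_cpg: np.ndarray | None = None
    _window_mre: np.ndarray | None = None

    @property
    def x_like(self) -> str:
        return self.config.x_like

    def window_site_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-flat-window CpG and MRE-site counts (cached)."""
        if self._window_cpg is None:
            cpg = np.zeros(len(self.frame), dtype=int)
            mre = np.zeros(len(self.frame), dtype=int)
            for chrom, length in self.chrom_sizes.items():
                nwin = self.frame.n_windows(chrom)
                edges = np.arange(nwin + 1) * self.frame.width
                edges[-1] = max(edges[-1], length)
                off = self.frame.flat_index(chrom, 0)
                cpg[off:off + nwin] = np.histogram(self.cpg_positions[chrom], bins=edges)[0]
                mre[off:off + nwin] = np.histogram(self.mre_site_positions[chrom], bins=edges)[0]
            self._window_cpg, self._window_mre = cpg, mre
        return self._window_cpg, self._window_mre


def _place_nonoverlapping(rng, length: int, n: int, sizes, occupied: list[tuple[int, int]],
                          max_tries: int = 2000) -> list[tuple[int, int]]:
    """Rejection-place n intervals of given sizes avoiding `occupied`."""
    placed = []
    taken = sorted(occupied)
    for size in sizes[:n]:
        for _ in range(max_tries):
            start = int(rng.integers(0, max(1, length - size)))
            end = start + size
            if all(end <= s or start >= e for s, e in taken):
                placed.append((start, end))
                taken.append((start, end))
                taken.sort()
                break
        else:
            raise ValueError("could not place annotations; config too dense for chromosome")
    return placed


def generate_genome(config: GenomeConfig | None = None, seed: int = 0) -> ToyGenome:
    """Deterministically generate a toy genome from a config and seed."""
    cfg = config or GenomeConfig()
    if cfg.x_like not in cfg.chrom_names:
        raise ValueError("x_like must be one of chrom_names")
    rng = np.random.default_rng(seed)
    chrom_sizes = {c: cfg.chrom_length for c in cfg.chrom_names}
    frame = window_frame(chrom_sizes, cfg.window)

    cgis: list[GenomicInterval] = []
    promoters: list[GenomicInterval] = []
    gene_bodies: list[GenomicInterval] = []
    exons: list[GenomicInterval] = []
    tss_lists: dict[str, list[tuple[str, int]]] = {
        "protein_coding": [], "miRNA": [], "lncRNA": [],
    }
    te_catalog: list[TEAnnotation] = []
    cpg_positions: dict[str, np.ndarray] = {}
    mre_positions: dict[str, np.ndarray] = {}

    for chrom in cfg.chrom_names:
        L = cfg.chrom_length
        # --- genes on a jittered grid, non-overlapping ---
        pos = int(rng.integers(20_000, 50_000))
        bodies = []
        for _ in range(cfg.n_genes_per_chrom):
            glen = int(rng.integers(*cfg.gene_length_range))
            if pos + glen + 2000 >= L:
                break
            bodies.append((pos, pos + glen))
            pos += glen + int(rng.integers(10_000, 35_000))
        for start, end in bodies:
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end  # most 5' TSS
            tss = min(max(tss, 500), L - 500)
            gene_bodies.append(GenomicInterval(chrom, start, end, strand=strand))
            promoters.append(GenomicInterval(chrom, tss - 500, tss + 500))
            tss_lists["protein_coding"].append((chrom, tss))
            n_ex = int(rng.integers(2, 5))
            ex_starts = np.sort(rng.integers(start, end - 300, size=n_ex))
            for es in ex_starts:
                exons.append(GenomicInterval(chrom, int(es), int(min(es + rng.integers(150, 400), end))))

        # --- CpG islands: ~60% at promoters, rest elsewhere ---
        sizes = [int(rng.integers(*cfg.cgi_length_range)) for _ in range(cfg.n_cgis_per_chrom)]
        n_prom_cgi = min(int(0.6 * cfg.n_cgis_per_chrom), len(bodies))
        occupied: list[tuple[int, int]] = []
        chrom_proms = [p for p in promoters if p.chrom == chrom]
        for i in range(n_prom_cgi):
            p = chrom_proms[i]
            center = (p.start + p.end) // 2
            half = sizes[i] // 2
            s, e = max(0, center - half), min(L, center - half + sizes[i])
            cgis.append(GenomicInterval(chrom, s, e))
            occupied.append((s, e))
        other = _place_nonoverlapping(
            rng, L, cfg.n_cgis_per_chrom - n_prom_cgi, sizes[n_prom_cgi:], occupied)
        for s, e in other:
            cgis.append(GenomicInterval(chrom, s, e))
            occupied.append((s, e))

        # --- transposable elements, avoiding CGIs ---
        for sub, (fam, cls, copies) in cfg.te_subfamilies.items():
            te_sizes = [int(rng.integers(*cfg.te_length_range)) for _ in range(copies)]
            spots = _place_nonoverlapping(rng, L, copies, te_sizes, occupied)
            for s, e in spots:
                te_catalog.append(TEAnnotation(GenomicInterval(chrom, s, e, name=sub), sub, fam, cls))
                occupied.append((s, e))

        # --- non-coding TSS lists (generic positions) ---
        for key, n in (("miRNA", cfg.n_mirna_tss_per_chrom), ("lncRNA", cfg.n_lncrna_tss_per_chrom)):
            for p in rng.integers(1000, L - 1000, size=n):
                tss_lists[key].append((chrom, int(p)))

        # --- CpGs: clustered background + dense CGIs ---
        n_centers = rng.poisson(cfg.bg_cluster_rate * L)
        centers = rng.uniform(0, L, size=n_centers)
        bg = []
        for c in centers:
            k = rng.poisson(cfg.bg_cluster_size_mean)
            bg.append(c + rng.normal(0, cfg.bg_cluster_sd, size=k))
        bg_pos = np.concatenate(bg) if bg else np.empty(0)
        cgi_pos = []
        for iv in cgis:
            if iv.chrom != chrom:
                continue
            k = rng.poisson(cfg.cgi_cpg_rate * len(iv))
            cgi_pos.append(rng.uniform(iv.start, iv.end, size=k))
        all_pos = np.concatenate([bg_pos] + cgi_pos) if cgi_pos else bg_pos
        all_pos = np.unique(all_pos.astype(int))
        all_pos = all_pos[(all_pos >= 0) & (all_pos < L)]
        cpg_positions[chrom] = all_pos
        n_mre = int(round(cfg.mre_fraction * all_pos.size))
        mre_positions[chrom] = np.sort(rng.choice(all_pos, size=n_mre, replace=False))

    return ToyGenome(
        cfg, chrom_sizes, frame, cpg_positions, mre_positions,
        cgis, promoters, gene_bodies, exons, tss_lists, te_catalog,
    )


@dataclass
class DMRDesign:
    """Counts, effect sizes, and baseline parameters for planted methylomes."""

    n_shared: int = 60
    n_eac: int = 60
    n_upsc: int = 60
    frac_hyper: float = 0.5
    delta_m: float = 0.6
    x_block_fraction: float = 0.5   # of the X-like chromosome
    x_block_delta: float = 0.3
    x_block_type: str = "UPSC"
    baseline_low: float = 0.1
    baseline_high: float = 0.8
    jitter_sd: float = 0.02         # window-level baseline jitter
    sample_jitter_sd: float = 0.01  # per-tumor-sample jitter
    plant_min_cpg_ratio: float = 2.0  # planted windows need cpg >= ratio x mean
    n_cnv_blocks_per_tumor: int = 2
    cnv_factors: tuple[float, ...] = (1.5, 0.75)
    cnv_block_length: int = 50_000


_H1_PATTERN = {
    ("hyper", "same"): "UUM", ("hyper", "high"): "MUM",
    ("hypo", "same"): "MMU", ("hypo", "low"): "UMU",
}


@dataclass(frozen=True)
class PlantedDMR:
    window_index: int
    interval: GenomicInterval
    direction: str        # hyper | hypo (tumor vs NE)
    affected: str         # "EAC" | "UPSC" | "shared"
    delta: float
    h1_state: str         # "same" | "high" | "low" (H1 relative to NE)

    @property
    def expected_pattern(self) -> str:
        return _H1_PATTERN[(self.direction, self.h1_state)]


@dataclass
class TruthSet:
    planted: list[PlantedDMR]
    x_block: GenomicInterval | None
    x_block_type: str
    x_block_delta: float
    design: DMRDesign

    def by_window(self) -> dict[int, PlantedDMR]:
        return {p.window_index: p for p in self.planted}

    def windows_of_class(self, affected: str) -> set[int]:
        return {p.window_index for p in self.planted if p.affected == affected}


@dataclass
class LatentMethylome:
    frame: WindowFrame
    samples: dict[str, np.ndarray]     # sample -> per-window m in [0,1]
    cnv: dict[str, np.ndarray]         # sample -> per-window copy-number factor
    groups: dict[str, str]             # sample -> NE / EAC / UPSC / H1

    def group_mean(self, group: str) -> np.ndarray:
        arrs = [m for s, m in self.samples.items() if self.groups[s] == group]
        return np.mean(arrs, axis=0)


def plant_methylomes(
    genome: ToyGenome, design: DMRDesign | None = None, seed: int = 0
) -> tuple[LatentMethylome, TruthSet]:
    """Build NE/tumor/H1 latent methylomes with planted differential windows."""
    design = design or DMRDesign()
    rng = np.random.default_rng(seed)
    frame = genome.frame
    n = len(frame)
    cpg, _ = genome.window_site_counts()
    cpg_mean = cpg.mean()

    low_idx = intervals_to_window_indices(genome.cgis + genome.promoters, frame)
    is_low = np.zeros(n, dtype=bool)
    is_low[list(low_idx)] = True

    baseline = np.where(is_low, design.baseline_low, design.baseline_high)
    baseline = np.clip(baseline + rng.normal(0, design.jitter_sd, size=n), 0.01, 0.99)

    # planting pools: CpG-dense windows off the X-like chromosome
    x_off = frame.flat_index(genome.x_like, 0)
    x_n = frame.n_windows(genome.x_like)
    on_x = np.zeros(n, dtype=bool)
    on_x[x_off:x_off + x_n] = True
    dense = cpg >= design.plant_min_cpg_ratio * cpg_mean
    hyper_pool = np.flatnonzero(is_low & dense & ~on_x)
    hypo_pool = np.flatnonzero(~is_low & dense & ~on_x)

    classes = [("shared", design.n_shared), ("EAC", design.n_eac), ("UPSC", design.n_upsc)]
    n_hyper_needed = sum(round(cnt * design.frac_hyper) for _, cnt in classes)
    n_hypo_needed = sum(cnt - round(cnt * design.frac_hyper) for _, cnt in classes)
    if n_hyper_needed > hyper_pool.size or n_hypo_needed > hypo_pool.size:
        raise ValueError(
            f"requested {n_hyper_needed} hyper / {n_hypo_needed} hypo planted windows "
            f"but pools hold {hyper_pool.size} / {hypo_pool.size}"
        )
    hyper_pick = rng.choice(hyper_pool, size=n_hyper_needed, replace=False)
    hypo_pick = rng.choice(hypo_pool, size=n_hypo_needed, replace=False)

    planted: list[PlantedDMR] = []
    hi = lo = 0
    for affected, cnt in classes:
        k_hyper = round(cnt * design.frac_hyper)
        for j in range(cnt):
            if j < k_hyper:
                w = int(hyper_pick[hi]); hi += 1
                direction = "hyper"
                h1_state = "same" if j % 2 == 0 else "high"
            else:
                w = int(hypo_pick[lo]); lo += 1
                direction = "hypo"
                h1_state = "same" if j % 2 == 0 else "low"
            planted.append(PlantedDMR(
                w, frame.windows[w].as_interval(), direction, affected,
                design.delta_m, h1_state))

    # X-like hypomethylated block (one cancer type only)
    x_block = None
    if design.x_block_fraction > 0:
        block_windows = int(round(design.x_block_fraction * x_n))
        start_w = int(rng.integers(0, x_n - block_windows + 1))
        s = start_w * frame.width
        e = min((start_w + block_windows) * frame.width, genome.chrom_sizes[genome.x_like])
        x_block = GenomicInterval(genome.x_like, s, e)

    samples: dict[str, np.ndarray] = {"NE": baseline.copy()}
    groups = {"NE": "NE", "H1": "H1"}
    cnv: dict[str, np.ndarray] = {"NE": np.ones(n)}

    truth = TruthSet(planted, x_block, design.x_block_type, design.x_block_delta, design)
    by_class: dict[str, list[PlantedDMR]] = {"shared": [], "EAC": [], "UPSC": []}
    for p in planted:
        by_class[p.affected].append(p)

    for name in TUMOR_SAMPLES:
        ttype = "EAC" if name in EAC_SAMPLES else "UPSC"
        m = baseline.copy()
        for p in by_class["shared"] + by_class[ttype]:
            m[p.window_index] += p.delta if p.direction == "hyper" else -p.delta
        if x_block is not None and ttype == design.x_block_type:
            idx = frame.overlapping_indices(x_block)
            m[idx] = np.maximum(m[idx] - design.x_block_delta, 0.01)
        m += rng.normal(0, design.sample_jitter_sd, size=n)
        samples[name] = np.clip(m, 0.005, 0.995)
        groups[name] = ttype
        # CNV blocks: multiplicative factor on expected counts of both assays
        factors = np.ones(n)
        for b in range(design.n_cnv_blocks_per_tumor):
            f = design.cnv_factors[b % len(design.cnv_factors)]
            chrom = list(genome.chrom_sizes)[int(rng.integers(0, len(genome.chrom_sizes)))]
            L = genome.chrom_sizes[chrom]
            s = int(rng.integers(0, L - design.cnv_block_length))
            idx = frame.overlapping_indices(GenomicInterval(chrom, s, s + design.cnv_block_length))
            factors[idx] = f
        cnv[name] = factors

    h1 = baseline.copy()
    for p in planted:
        if p.h1_state == "high":
            h1[p.window_index] = min(h1[p.window_index] + p.delta, 0.99)
        elif p.h1_state == "low":
            h1[p.window_index] = max(h1[p.window_index] - p.delta, 0.01)
    h1 += rng.normal(0, design.sample_jitter_sd, size=n)
    samples["H1"] = np.clip(h1, 0.005, 0.995)
    cnv["H1"] = np.ones(n)

    return LatentMethylome(frame, samples, cnv, groups), truth


@dataclass
class DepthConfig:
    """Expected reads per window per assay at reference CpG density, m = 1."""
    medip_depth: float = 30.0
    mre_depth: float = 30.0


def simulate_counts(
    latent: LatentMethylome,
    genome: ToyGenome,
    depth: DepthConfig | None = None,
    seed: int = 0,
) -> dict[str, WindowedCountTrack]:
    """Draw Poisson MeDIP/MRE counts per window for every sample.

    MeDIP rate:  depth * cnv * m * cpg_count / mean_cpg
    MRE rate:    depth * cnv * (1 - m) * mre_site_count / mean_mre
    Windows without CpGs get zero counts in both assays.
    """
    depth = depth or DepthConfig()
    if depth.medip_depth < 0 or depth.mre_depth < 0:
        raise ValueError("depth must be non-negative")
    rng = np.random.default_rng(seed)
    cpg, mre = genome.window_site_counts()
    cpg_ref = max(cpg.mean(), 1e-12)
    mre_ref = max(mre.mean(), 1e-12)
    tracks = {}
    for name, m in latent.samples.items():
        cnv = latent.cnv[name]
        lam_medip = depth.medip_depth * cnv * m * (cpg / cpg_ref)
        lam_mre = depth.mre_depth * cnv * (1.0 - m) * (mre / mre_ref)
        tracks[name] = WindowedCountTrack(
            sample_id=name, frame=latent.frame,
            medip=rng.poisson(lam_medip),
            mre=rng.poisson(lam_mre),
            cpg_count=cpg.copy(), mre_site_count=mre.copy(),
            cnv_factor=cnv.copy(),
        )
    return tracks


@dataclass
class CohortConfig:
    n_normal: int = 20
    n_eac: int = 20
    n_upsc: int = 20
    probes_per_kb: float = 0.5
    cgi_bias: float = 3.0        # probe-density multiplier in CGI/promoter windows
    precision: float = 50.0      # Beta-distribution concentration; inf = noiseless
    zero_probe_fraction: float = 0.3  # planted DMR windows left without probes
    missing_rate: float = 0.0


def simulate_probe_cohort(
    latent: LatentMethylome,
    genome: ToyGenome,
    truth: TruthSet | None = None,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> BetaCohort:
    """An Infinium-like validation cohort: probe manifest + beta matrix.

    Probes are placed with a density bias toward CGI/promoter windows
    (arrays target regulatory regions); a configurable fraction of planted
    DMR windows is deliberately left probe-free to exercise the coverage
    reporting. Betas are Beta-distributed around the group's latent
    methylation at the probe's window.
    """
    cfg = config or CohortConfig()
    if min(cfg.n_normal, cfg.n_eac, cfg.n_upsc) <= 0:
        raise ValueError("every cohort group needs >= 1 sample")
    rng = np.random.default_rng(seed)
    frame = latent.frame
    n = len(frame)

    low_idx = intervals_to_window_indices(genome.cgis + genome.promoters, frame)
    weights = np.ones(n)
    weights[list(low_idx)] = cfg.cgi_bias

    blocked: set[int] = set()
    if truth is not None and cfg.zero_probe_fraction > 0:
        planted_windows = [p.window_index for p in truth.planted]
        k = int(round(cfg.zero_probe_fraction * len(planted_windows)))
        blocked = set(rng.choice(planted_windows, size=k, replace=False).tolist())
        weights[list(blocked)] = 0.0

    genome_kb = sum(genome.chrom_sizes.values()) / 1000.0
    n_probes = int(round(cfg.probes_per_kb * genome_kb))
    probs = weights / weights.sum()
    probe_windows = rng.choice(n, size=n_probes, replace=True, p=probs)
    rows = []
    for j, w in enumerate(np.sort(probe_windows)):
        win = frame.windows[int(w)]
        pos = int(rng.integers(win.start, win.end))
        rows.append((f"cg{j:06d}", win.chrom, pos, int(w)))
    manifest = pd.DataFrame(rows, columns=["probe_id", "chrom", "position", "window_index"])

    profiles = {
        "normal": latent.samples["NE"],
        "EAC-like": latent.group_mean("EAC"),
        "UPSC-like": latent.group_mean("UPSC"),
    }
    group_sizes = {"normal": cfg.n_normal, "EAC-like": cfg.n_eac, "UPSC-like": cfg.n_upsc}
    cols, groups = [], {}
    data = {}
    widx = manifest["window_index"].to_numpy()
    for g, size in group_sizes.items():
        mu = np.clip(profiles[g][widx], 1e-3, 1 - 1e-3)
        for i in range(size):
            sid = f"{g.replace('-like', '')}_{i:02d}"
            if np.isinf(cfg.precision):
                beta = mu.copy()
            else:
                beta = rng.beta(mu * cfg.precision, (1 - mu) * cfg.precision)
            if cfg.missing_rate > 0:
                beta = beta.copy()
                beta[rng.random(beta.size) < cfg.missing_rate] = np.nan
            data[sid] = beta
            cols.append(sid)
            groups[sid] = g
    beta_df = pd.DataFrame(data, index=manifest["probe_id"])
    return BetaCohort(manifest.drop(columns="window_index"), beta_df, groups)


CHROMHMM_STATES = ("Tss", "Enh", "Txn", "ReprPC", "Quies")


def default_state_map() -> dict[str, str]:
    return {"Tss": "promoter", "Enh": "enhancer",
            "Txn": "other", "ReprPC": "other", "Quies": "other"}


def simulate_chromhmm(
    genome: ToyGenome,
    n_cell_lines: int = 2,
    seed: int = 0,
    res: int = 50,
    n_random_enhancers_per_chrom: int = 30,
) -> dict[str, list[ChromHMMSegment]]:
    """Per-cell-line chromatin-state segmentations tiling each chromosome.

    Promoter states are planted at TSSs (with high per-line probability)
    and enhancer states at enhancer-designated TE copies plus random
    intergenic patches, over a background of geometric-length segments of
    neutral states.
    """
    if n_cell_lines < 2:
        raise ValueError("need >= 2 cell lines")
    rng = np.random.default_rng(seed)
    cfg = genome.config
    enhancer_tes = [t.interval for t in genome.te_catalog
                    if t.subfamily in cfg.enhancer_te_subfamilies]
    out: dict[str, list[ChromHMMSegment]] = {}
    background = ["Txn", "ReprPC", "Quies"]
    for ci in range(n_cell_lines):
        cell = f"cell{ci + 1}"
        segs: list[ChromHMMSegment] = []
        for chrom, L in genome.chrom_sizes.items():
            ncell = -(-L // res)
            state = np.empty(ncell, dtype=object)
            i = 0
            while i < ncell:
                run = 1 + rng.geometric(1 / 40)  # mean segment ~2 kb at res 50
                state[i:i + run] = background[int(rng.integers(0, len(background)))]
                i += run
            for c, tss in genome.tss_lists["protein_coding"]:
                if c == chrom and rng.random() < 0.9:
                    state[max(0, (tss - 500) // res):min(ncell, -(-(tss + 500) // res))] = "Tss"
            for iv in enhancer_tes:
                if iv.chrom == chrom and rng.random() < 0.7:
                    state[iv.start // res:-(-iv.end // res)] = "Enh"
            for _ in range(n_random_enhancers_per_chrom):
                s = int(rng.integers(0, ncell - 10))
                if not (state[s:s + 10] == "Tss").any():
                    state[s:s + 10] = "Enh"
            # compress runs into segments
            change = np.flatnonzero(state[1:] != state[:-1]) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [ncell]])
            for s, e in zip(starts, ends):
                segs.append(ChromHMMSegment(
                    GenomicInterval(chrom, int(s * res), int(min(e * res, L))),
                    str(state[s]), cell))
        out[cell] = segs
    return out
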