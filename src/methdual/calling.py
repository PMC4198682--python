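"""Dual-assay differential methylation calling on a fixed window frame.

Each 500 bp window carries MeDIP read counts (signal increases with
methylated-CpG density) and MRE read counts (fragment-end reads at
*unmethylated* CpG sites, anti-correlated with MeDIP). A tumor/normal pair
is tested per window with a conditional-binomial score per assay combined
by a signed Stouffer statistic with the MRE sign flipped; windows passing
a Benjamini-Hochberg q-value cutoff (default 1e-5) become DMR calls.
Recurrence rules then build per-type consensus DMRs (same direction in
>= 2 of 3 tumor-vs-normal comparisons), DMRs shared by both cancer types,
and type-preferred DMRs (all 3 of one type, none of the other).

Copy-number variation enters as a multiplicative exposure offset: the
effective exposure of a window is ``library_total * cnv_factor``, which
shifts the conditional-binomial null proportion rather than rescaling the
observed counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomicInterval, WindowFrame

__all__ = [
    "WindowedCountTrack",
    "DMRCall",
    "ConsensusDMR",
    "pool_mre_enzymes",
    "normalize_track",
    "window_test",
    "window_test_arrays",
    "bh_adjust",
    "pairwise_test",
    "call_pairwise_dmrs",
    "consensus_dmrs",
    "shared_dmrs",
    "type_preferred_dmrs",
]

_P_FLOOR = 1e-300  # tail floor before the inverse-normal map, avoids infinities


@dataclass
class WindowedCountTrack:
    """Per-window MeDIP/MRE read counts for one sample on a shared frame."""

    sample_id: str
    frame: WindowFrame
    medip: np.ndarray
    mre: np.ndarray
    cpg_count: np.ndarray
    mre_site_count: np.ndarray
    cnv_factor: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.frame)
        for name in ("medip", "mre", "cpg_count", "mre_site_count"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({n},)")
            if (arr < 0).any():
                raise ValueError(f"{name} contains negative values")
            setattr(self, name, arr)
        if self.cnv_factor is None:
            self.cnv_factor = np.ones(n)
        else:
            self.cnv_factor = np.asarray(self.cnv_factor, dtype=float)
            if self.cnv_factor.shape != (n,):
                raise ValueError("cnv_factor shape mismatch")
            if (self.cnv_factor <= 0).any():
                raise ValueError("cnv_factor must be positive")

    @property
    def medip_total(self) -> int:
        return int(self.medip.sum())

    @property
    def mre_total(self) -> int:
        return int(self.mre.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = [(w.chrom, w.start, w.end) for w in self.frame.windows]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["medip"] = self.medip
        df["mre"] = self.mre
        df["cpg_count"] = self.cpg_count
        df["mre_site_count"] = self.mre_site_count
        return df


@dataclass(frozen=True)
class DMRCall:
    """A significant per-window call from one tumor-vs-normal comparison."""

    window_index: int
    interval: GenomicInterval
    comparison: str
    statistic: float
    p_value: float
    q_value: float
    direction: str  # "hyper" | "hypo"


@dataclass(frozen=True)
class ConsensusDMR:
    """A window-level DMR after the recurrence / shared / type-preferred rules."""

    window_index: int
    interval: GenomicInterval
    cancer_type: str  # "EAC" | "UPSC" | "EC-shared"
    direction: str
    support: int
    q_value: float
    tp_flag: bool = False


def pool_mre_enzymes(counts_by_enzyme: Mapping[str, np.ndarray]) -> np.ndarray:
    """Rescale each enzyme's counts to equal per-enzyme totals, then pool.

    Differences in restriction-enzyme efficiency make raw per-enzyme read
    totals incomparable; each enzyme track is scaled to the mean total
    before summation.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in counts_by_enzyme.items()}
    totals = {k: a.sum() for k, a in arrays.items()}
    if any(t <= 0 for t in totals.values()):
        raise ValueError("each enzyme track needs a positive total")
    target = float(np.mean(list(totals.values())))
    pooled = sum(a * (target / totals[k]) for k, a in arrays.items())
    return pooled


def normalize_track(track: WindowedCountTrack) -> dict[str, np.ndarray]:
    """Per-window effective exposures (library total x CNV factor) per assay.

    Raw counts are left untouched; the exposures feed the conditional null
    of :func:`window_test`.
    """
    if track.medip_total <= 0 or track.mre_total <= 0:
        raise ValueError(f"{track.sample_id}: zero library total")
    return {
        "medip": track.medip_total * track.cnv_factor,
        "mre": track.mre_total * track.cnv_factor,
    }


def _signed_z(x_t: np.ndarray, total: np.ndarray, p0: np.ndarray) -> np.ndarray:
    """Signed normal score of tumor counts under Binomial(total, p0).

    Positive = tumor enriched. The one-sided tail in the direction of the
    deviation is mapped through the inverse normal; total == 0 gives 0.
    """
    x_t = np.asarray(x_t, dtype=float)
    total = np.asarray(total, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    z = np.zeros_like(x_t, dtype=float)
    pos = total > 0
    if not pos.any():
        return z
    xt, tt, pp = x_t[pos], total[pos], p0[pos]
    p_up = stats.binom.sf(xt - 1, tt, pp)   # P[X >= x_t]
    p_down = stats.binom.cdf(xt, tt, pp)    # P[X <= x_t]
    up = p_up < p_down
    tail = np.where(up, p_up, p_down)
    zz = stats.norm.isf(np.maximum(tail, _P_FLOOR))
    signed = np.where(up, zz, -zz)
    signed[p_up == p_down] = 0.0  # observation at the exact null center
    z[pos] = signed
    return z


def window_test_arrays(
    x_n: np.ndarray, x_t: np.ndarray,
    y_n: np.ndarray, y_t: np.ndarray,
    s_n_medip: np.ndarray, s_t_medip: np.ndarray,
    s_n_mre: np.ndarray, s_t_mre: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized dual-assay window test.

    Returns ``(statistic, p_value)`` arrays. The statistic is
    ``(z_MeDIP - z_MRE)/sqrt(2)`` (MRE sign flipped: MRE reads mark
    unmethylated CpGs), falling back to the single available assay's score
    when the other has a zero per-window margin. p-values are two-sided
    from the standard normal.
    """
    x_n, x_t = np.asarray(x_n, float), np.asarray(x_t, float)
    y_n, y_t = np.asarray(y_n, float), np.asarray(y_t, float)
    t_m = x_n + x_t
    t_r = y_n + y_t
    p0_m = np.divide(s_t_medip, s_n_medip + s_t_medip,
                     out=np.full_like(t_m, 0.5), where=(s_n_medip + s_t_medip) > 0)
    p0_r = np.divide(s_t_mre, s_n_mre + s_t_mre,
                     out=np.full_like(t_r, 0.5), where=(s_n_mre + s_t_mre) > 0)
    z_m = _signed_z(x_t, t_m, p0_m)
    z_r = _signed_z(y_t, t_r, p0_r)
    has_m = t_m > 0
    has_r = t_r > 0
    both = has_m & has_r
    stat = np.zeros_like(z_m)
    stat[both] = (z_m[both] - z_r[both]) / np.sqrt(2.0)
    only_m = has_m & ~has_r
    stat[only_m] = z_m[only_m]
    only_r = has_r & ~has_m
    stat[only_r] = -z_r[only_r]
    p = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(stat)))
    p[~(has_m | has_r)] = 1.0
    return stat, p


def window_test(
    x_n: int, x_t: int, y_n: int, y_t: int,
    s_n_medip: float = 1.0, s_t_medip: float = 1.0,
    s_n_mre: float = 1.0, s_t_mre: float = 1.0,
) -> tuple[float, float, str]:
    """Scalar window test; returns ``(statistic, p_value, direction)``."""
    stat, p = window_test_arrays(
        np.array([x_n]), np.array([x_t]), np.array([y_n]), np.array([y_t]),
        np.array([s_n_medip], float), np.array([s_t_medip], float),
        np.array([s_n_mre], float), np.array([s_t_mre], float),
    )
    direction = "hyper" if stat[0] > 0 else "hypo"
    return float(stat[0]), float(p[0]), direction


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _check_same_frame(a: WindowedCountTrack, b: WindowedCountTrack) -> None:
    if a.frame.chrom_sizes != b.frame.chrom_sizes or a.frame.width != b.frame.width:
        raise ValueError("tracks are on different window frames")
    if not np.array_equal(a.cpg_count, b.cpg_count):
        raise ValueError("tracks disagree on per-window CpG counts")


def pairwise_test(normal: WindowedCountTrack, tumor: WindowedCountTrack) -> pd.DataFrame:
    """Test every CpG-containing window of a tumor-vs-normal pair.

    Windows with ``cpg_count == 0`` are excluded both from testing and from
    the BH family (both assays are CpG-conditional, so such windows carry
    no evidence). Returns a DataFrame indexed by flat window index with
    columns statistic / p_value / q_value / direction.
    """
    _check_same_frame(normal, tumor)
    exp_n = normalize_track(normal)
    exp_t = normalize_track(tumor)
    tested = np.flatnonzero(normal.cpg_count > 0)
    stat, p = window_test_arrays(
        normal.medip[tested], tumor.medip[tested],
        normal.mre[tested], tumor.mre[tested],
        exp_n["medip"][tested], exp_t["medip"][tested],
        exp_n["mre"][tested], exp_t["mre"][tested],
    )
    q = bh_adjust(p)
    direction = np.where(stat > 0, "hyper", "hypo")
    return pd.DataFrame(
        {"statistic": stat, "p_value": p, "q_value": q, "direction": direction},
        index=pd.Index(tested, name="window_index"),
    )


def call_pairwise_dmrs(
    normal: WindowedCountTrack,
    tumor: WindowedCountTrack,
    q_cutoff: float = 1e-5,
    comparison: str | None = None,
) -> list[DMRCall]:
    """Windows with BH q-value below ``q_cutoff`` for one comparison."""
    res = pairwise_test(normal, tumor)
    hits = res[res["q_value"] < q_cutoff]
    label = comparison or f"{tumor.sample_id}_vs_{normal.sample_id}"
    calls = []
    for idx, row in hits.iterrows():
        w = normal.frame.windows[idx]
        calls.append(DMRCall(
            int(idx), w.as_interval(), label,
            float(row["statistic"]), float(row["p_value"]),
            float(row["q_value"]), str(row["direction"]),
        ))
    return calls


def _calls_by_window(calls: Sequence[DMRCall]) -> dict[int, DMRCall]:
    return {c.window_index: c for c in calls}


def consensus_dmrs(
    call_sets: Sequence[Sequence[DMRCall]],
    cancer_type: str,
    frame: WindowFrame,
    min_support: int = 2,
) -> list[ConsensusDMR]:
    """Recurrence consensus: same direction in >= ``min_support`` comparisons.

    Direction conflicts resolve to the strict majority direction provided
    the majority count itself reaches ``min_support``; exact ties yield no
    call.
    """
    per_set = [_calls_by_window(cs) for cs in call_sets]
    windows = sorted(set().union(*[set(d) for d in per_set]) if per_set else set())
    out = []
    for w in windows:
        calls = [d[w] for d in per_set if w in d]
        n_hyper = sum(c.direction == "hyper" for c in calls)
        n_hypo = len(calls) - n_hyper
        if n_hyper == n_hypo:
            continue
        direction = "hyper" if n_hyper > n_hypo else "hypo"
        support = max(n_hyper, n_hypo)
        if support < min_support:
            continue
        q = min(c.q_value for c in calls if c.direction == direction)
        out.append(ConsensusDMR(w, frame.windows[w].as_interval(),
                                cancer_type, direction, support, q))
    return out


def shared_dmrs(
    eac_consensus: Sequence[ConsensusDMR],
    upsc_consensus: Sequence[ConsensusDMR],
) -> list[ConsensusDMR]:
    """Windows that are consensus DMRs in both types with identical direction."""
    upsc = {d.window_index: d for d in upsc_consensus}
    out = []
    for e in eac_consensus:
        u = upsc.get(e.window_index)
        if u is not None and u.direction == e.direction:
            out.append(ConsensusDMR(
                e.window_index, e.interval, "EC-shared", e.direction,
                min(e.support, u.support), min(e.q_value, u.q_value),
            ))
    return out


def type_preferred_dmrs(
    eac_call_sets: Sequence[Sequence[DMRCall]],
    upsc_call_sets: Sequence[Sequence[DMRCall]],
    frame: WindowFrame,
) -> tuple[list[ConsensusDMR], list[ConsensusDMR]]:
    """Type-preferred DMRs: called (same direction) in every comparison of
    one type and in no comparison of the other (either direction)."""

    def tp(own: Sequence[Sequence[DMRCall]], other: Sequence[Sequence[DMRCall]],
           label: str) -> list[ConsensusDMR]:
        own_maps = [_calls_by_window(cs) for cs in own]
        other_called: set[int] = set().union(*[set(_calls_by_window(cs)) for cs in other]) \
            if other else set()
        if not own_maps:
            return []
        candidates = set(own_maps[0])
        for d in own_maps[1:]:
            candidates &= set(d)
        out = []
        for w in sorted(candidates - other_called):
            dirs = {d[w].direction for d in own_maps}
            if len(dirs) != 1:
                continue
            q = min(d[w].q_value for d in own_maps)
            out.append(ConsensusDMR(w, frame.windows[w].as_interval(),
                                    label, dirs.pop(), len(own_maps), q, tp_flag=True))
        return out

    return (tp(eac_call_sets, upsc_call_sets, "EAC"),
            tp(upsc_call_sets, eac_call_sets, "UPSC"))
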