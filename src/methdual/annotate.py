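"""Regulatory and genomic-context annotation of consensus DMRs.

Covers: exclusive genomic-context labels (promoter > exon/UTR > intron >
intergenic priority, with CGI/shore/TE flags carried independently),
window-based feature enrichment scores, CpG-island/shore change patterns,
chromHMM dominant-state merging across cell lines, developmental
methylation-state words (MMU/MUM/UMU/UUM across ES cells, normal tissue,
and cancer), transposable-element subfamily enrichment, and
chromosome-scale RPKM / density profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import ConsensusDMR, WindowedCountTrack, bh_adjust
from .genome import (
    ChromHMMSegment,
    GenomicInterval,
    TEAnnotation,
    WindowFrame,
    intervals_to_window_indices,
    overlap_any,
    overlap_join,
)

__all__ = [
    "FeatureCatalog",
    "EnrichmentResult",
    "classify_context",
    "feature_enrichment",
    "feature_enrichment_batch",
    "cgi_shore_patterns",
    "dominant_state",
    "merge_states",
    "regulatory_class_of_windows",
    "methylation_pattern",
    "h1_comparison_of_windows",
    "te_enrichment_report",
    "binned_rpkm_profile",
    "global_density_shift",
]


def _shores_for_cgi(cgi: GenomicInterval, all_cgis: Sequence[GenomicInterval],
                    chrom_length: int, flank: int = 1000) -> list[GenomicInterval]:
    """The 1 kb flanks of a CGI, clipped to the chromosome and minus any CGI body."""
    raw = []
    if cgi.start > 0:
        raw.append((max(0, cgi.start - flank), cgi.start))
    if cgi.end < chrom_length:
        raw.append((cgi.end, min(chrom_length, cgi.end + flank)))
    pieces = []
    for s, e in raw:
        cuts = [(s, e)]
        for other in all_cgis:
            if other.chrom != cgi.chrom:
                continue
            nxt = []
            for ps, pe in cuts:
                if other.end <= ps or other.start >= pe:
                    nxt.append((ps, pe))
                else:
                    if ps < other.start:
                        nxt.append((ps, other.start))
                    if other.end < pe:
                        nxt.append((other.end, pe))
            cuts = nxt
        pieces.extend(cuts)
    return [GenomicInterval(cgi.chrom, s, e) for s, e in pieces if e > s]


@dataclass
class FeatureCatalog:
    """Genomic features used for context labels and enrichment."""

    chrom_sizes: dict[str, int]
    cgis: list[GenomicInterval]
    core_promoters: list[GenomicInterval]
    gene_bodies: list[GenomicInterval]
    exons: list[GenomicInterval]
    te_catalog: list[TEAnnotation]
    shores_by_cgi: list[list[GenomicInterval]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.shores_by_cgi:
            self.shores_by_cgi = [
                _shores_for_cgi(c, self.cgis, self.chrom_sizes[c.chrom])
                for c in self.cgis
            ]

    @property
    def shores(self) -> list[GenomicInterval]:
        return [s for group in self.shores_by_cgi for s in group]

    @property
    def te_intervals(self) -> list[GenomicInterval]:
        return [t.interval for t in self.te_catalog]

    @classmethod
    def from_genome(cls, genome) -> "FeatureCatalog":
        return cls(
            chrom_sizes=dict(genome.chrom_sizes),
            cgis=list(genome.cgis),
            core_promoters=list(genome.promoters),
            gene_bodies=list(genome.gene_bodies),
            exons=list(genome.exons),
            te_catalog=list(genome.te_catalog),
        )


def classify_context(dmr: GenomicInterval, catalog: FeatureCatalog) -> dict:
    """Exclusive context label plus independent CGI/shore/TE membership flags.

    The exclusive label follows the priority promoter > exon/UTR > intron >
    intergenic; a DMR inside a gene body but outside every exon counts as
    intronic.
    """
    [in_prom] = overlap_any([dmr], catalog.core_promoters)
    [in_exon] = overlap_any([dmr], catalog.exons)
    [in_body] = overlap_any([dmr], catalog.gene_bodies)
    if in_prom:
        label = "promoter"
    elif in_exon:
        label = "exon"
    elif in_body:
        label = "intron"
    else:
        label = "intergenic"
    [in_cgi] = overlap_any([dmr], catalog.cgis)
    [in_shore] = overlap_any([dmr], catalog.shores)
    [in_te] = overlap_any([dmr], catalog.te_intervals)
    return {"context": label, "in_cgi": in_cgi, "in_shore": in_shore, "in_te": in_te}


@dataclass
class EnrichmentResult:
    """Window-based enrichment of a feature among DMR windows.

    ES = (n_hit / n_DMR) / (N_hit / N_all): the feature frequency among DMR
    windows over its genome-wide window frequency.
    """

    feature: str
    n_hit: int
    n_dmr: int
    N_hit: int
    N_all: int
    es: float | None
    p_value: float | None
    q_value: float | None = None
    flag_5fold: bool = False


def feature_enrichment(
    dmr_windows: set[int], feature: str, feature_windows: set[int], n_all_windows: int
) -> EnrichmentResult:
    """ES plus a one-sided binomial p-value (success prob = genome rate)."""
    n_dmr = len(dmr_windows)
    if n_dmr == 0:
        raise ValueError("n_DMR must be positive")
    N_hit = len(feature_windows)
    n_hit = len(dmr_windows & feature_windows)
    if N_hit == 0:
        return EnrichmentResult(feature, n_hit, n_dmr, 0, n_all_windows, None, None)
    es = (n_hit / n_dmr) / (N_hit / n_all_windows)
    p = float(stats.binom.sf(n_hit - 1, n_dmr, N_hit / n_all_windows))
    return EnrichmentResult(feature, n_hit, n_dmr, N_hit, n_all_windows, es, p)


def feature_enrichment_batch(
    dmr_windows: set[int],
    features: Mapping[str, set[int]],
    n_all_windows: int,
    q_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Enrichment for a batch of features with BH correction across the batch."""
    results = [feature_enrichment(dmr_windows, name, wins, n_all_windows)
               for name, wins in features.items()]
    testable = [r for r in results if r.p_value is not None]
    if testable:
        q = bh_adjust([r.p_value for r in testable])
        for r, qi in zip(testable, q):
            r.q_value = float(qi)
            r.flag_5fold = (r.es is not None and r.es > 5.0 and r.q_value < q_threshold)
    return results


def cgi_shore_patterns(
    catalog: FeatureCatalog,
    dmrs_by_direction: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Per-CGI, per-direction category: CGI-only / CGI+shore / shore-only / none.

    A CGI is changed "at CGI" for a direction iff >= 1 DMR window of that
    direction overlaps the island body, and "at shore" iff one overlaps
    either flank (flanks exclude neighboring CGI bodies); directions are
    partitioned independently.
    """
    rows = []
    for direction, dmrs in dmrs_by_direction.items():
        body_hit = overlap_any(catalog.cgis, list(dmrs))
        for i, cgi in enumerate(catalog.cgis):
            shore_hit = any(overlap_any(catalog.shores_by_cgi[i], list(dmrs))) \
                if catalog.shores_by_cgi[i] else False
            if body_hit[i] and shore_hit:
                cat = "CGI+shore"
            elif body_hit[i]:
                cat = "CGI-only"
            elif shore_hit:
                cat = "shore-only"
            else:
                cat = "none"
            rows.append({"cgi_index": i, "chrom": cgi.chrom, "start": cgi.start,
                         "end": cgi.end, "direction": direction, "category": cat})
    return pd.DataFrame(rows)


def dominant_state(
    window: GenomicInterval, segments: Sequence[ChromHMMSegment]
) -> str | None:
    """The chromatin state covering > 50% of the window's bases, else None."""
    cover: dict[str, int] = {}
    hits = overlap_join([window], [s.interval for s in segments])[0]
    for j, length in hits:
        cover[segments[j].state] = cover.get(segments[j].state, 0) + length
    half = len(window) / 2.0
    for state, bases in cover.items():
        if bases > half:
            return state
    return None


def merge_states(
    dominant_states: Iterable[str | None], state_map: Mapping[str, str]
) -> str:
    """Merge per-cell-line dominant states into promoter/enhancer/other.

    Promoter takes precedence: a window with a promoter-type dominant
    state in any cell line is "promoter"; an enhancer-type state in any
    line without promoter anywhere is "enhancer"; otherwise "other".
    """
    classes = set()
    for s in dominant_states:
        if s is None:
            continue
        if s not in state_map:
            raise KeyError(f"state {s!r} missing from state_map")
        classes.add(state_map[s])
    if "promoter" in classes:
        return "promoter"
    if "enhancer" in classes:
        return "enhancer"
    return "other"


def regulatory_class_of_windows(
    windows: Sequence[GenomicInterval],
    segments_by_cell_line: Mapping[str, Sequence[ChromHMMSegment]],
    state_map: Mapping[str, str],
) -> list[str]:
    """Vectorized-ish merge of dominant states across cell lines per window."""
    per_line_doms: list[list[str | None]] = []
    for cell, segs in segments_by_cell_line.items():
        seg_ivs = [s.interval for s in segs]
        joins = overlap_join(list(windows), seg_ivs)
        doms = []
        for w, hits in zip(windows, joins):
            cover: dict[str, int] = {}
            for j, length in hits:
                cover[segs[j].state] = cover.get(segs[j].state, 0) + length
            half = len(w) / 2.0
            dom = None
            for state, bases in cover.items():
                if bases > half:
                    dom = state
                    break
            doms.append(dom)
        per_line_doms.append(doms)
    return [merge_states([doms[i] for doms in per_line_doms], state_map)
            for i in range(len(windows))]


_PATTERN_MAP = {
    ("hypo", "none"): "MMU",
    ("hypo", "NE-higher"): "UMU",
    ("hyper", "none"): "UUM",
    ("hyper", "NE-lower"): "MUM",
}


def methylation_pattern(cancer_direction: str, h1_vs_ne_call: str) -> str | None:
    """Three-state word across ES cells / normal endometrium / cancer.

    ``h1_vs_ne_call`` describes the normal tissue relative to H1 at the
    window: "NE-higher" (normal methylated above ESC), "NE-lower", or
    "none" (no difference). Combinations outside the four canonical words
    (M/U triplets whose normal and cancer states coincide) return None.
    """
    if cancer_direction not in {"hyper", "hypo"}:
        raise ValueError(f"bad direction {cancer_direction!r}")
    if h1_vs_ne_call not in {"NE-higher", "NE-lower", "none"}:
        raise ValueError(f"bad H1 comparison {h1_vs_ne_call!r}")
    return _PATTERN_MAP.get((cancer_direction, h1_vs_ne_call))


def h1_comparison_of_windows(
    h1_calls: Mapping[int, str], window_indices: Iterable[int]
) -> dict[int, str]:
    """Map per-window H1-vs-NE call directions to NE-relative labels.

    ``h1_calls`` holds the direction of significant H1-vs-NE windows with
    NE as the baseline ("hyper" = H1 above NE). Windows without a call are
    "none".
    """
    out = {}
    for w in window_indices:
        d = h1_calls.get(w)
        out[w] = "none" if d is None else ("NE-lower" if d == "hyper" else "NE-higher")
    return out


def te_enrichment_report(
    consensus: Sequence[ConsensusDMR],
    te_catalog: Sequence[TEAnnotation],
    frame: WindowFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overall TE-overlap fractions and per-subfamily enrichment per direction.

    Returns ``(fractions, subfamily_table)``: fractions of hyper and hypo
    DMRs overlapping any TE copy, and per-subfamily ES (with BH q and the
    >5-fold significance flag) computed separately for hyper and hypo DMR
    window sets.
    """
    n_all = len(frame)
    subfam_windows: dict[str, set[int]] = {}
    for t in te_catalog:
        subfam_windows.setdefault(t.subfamily, set()).update(
            frame.overlapping_indices(t.interval))
    all_te = set().union(*subfam_windows.values()) if subfam_windows else set()

    frac_rows, sub_rows = [], []
    for direction in ("hyper", "hypo"):
        dmr_w = {d.window_index for d in consensus if d.direction == direction}
        if not dmr_w:
            frac_rows.append({"direction": direction, "n_dmrs": 0, "te_fraction": 0.0})
            continue
        frac = len(dmr_w & all_te) / len(dmr_w)
        frac_rows.append({"direction": direction, "n_dmrs": len(dmr_w), "te_fraction": frac})
        for r in feature_enrichment_batch(dmr_w, subfam_windows, n_all):
            sub_rows.append({
                "direction": direction, "subfamily": r.feature, "n_hit": r.n_hit,
                "n_dmr": r.n_dmr, "N_hit": r.N_hit, "es": r.es,
                "p_value": r.p_value, "q_value": r.q_value, "flag_5fold": r.flag_5fold,
            })
    return pd.DataFrame(frac_rows), pd.DataFrame(sub_rows)


def _bin_counts(track: WindowedCountTrack, assay: str, bin_width: int) -> pd.DataFrame:
    if bin_width % track.frame.width != 0:
        raise ValueError("bin width must be a multiple of the window width")
    counts = getattr(track, assay)
    rows = []
    for chrom in track.frame.chrom_sizes:
        off = track.frame.flat_index(chrom, 0)
        nwin = track.frame.n_windows(chrom)
        per_bin = bin_width // track.frame.width
        chrom_counts = counts[off:off + nwin]
        n_bins = -(-nwin // per_bin)
        for b in range(n_bins):
            c = int(chrom_counts[b * per_bin:(b + 1) * per_bin].sum())
            start = b * bin_width
            end = min((b + 1) * bin_width, track.frame.chrom_sizes[chrom])
            rows.append((chrom, start, end, c))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


def binned_rpkm_profile(
    normal: WindowedCountTrack,
    tumors: Sequence[WindowedCountTrack],
    assay: str = "medip",
    bin_width: int = 500_000,
) -> pd.DataFrame:
    """Large-bin RPKM per sample and the type-averaged log2 fold change.

    RPKM = count / (bin_kb * library_millions). Fold changes
    (tumor / normal) are averaged across the tumor tracks first and then
    log2-transformed; bins with zero normal RPKM are reported missing.
    """
    nb = _bin_counts(normal, assay, bin_width)
    lib_n = getattr(normal, f"{assay}_total") / 1e6
    if lib_n <= 0:
        raise ValueError("library total must be positive")
    bin_kb = (nb["end"] - nb["start"]) / 1000.0
    out = nb[["chrom", "start", "end"]].copy()
    out["rpkm_normal"] = nb["count"] / (bin_kb * lib_n)
    fold_sum = np.zeros(len(nb))
    for t in tumors:
        tb = _bin_counts(t, assay, bin_width)
        lib_t = getattr(t, f"{assay}_total") / 1e6
        rpkm_t = tb["count"] / (bin_kb * lib_t)
        fold_sum += np.where(out["rpkm_normal"] > 0, rpkm_t / out["rpkm_normal"], np.nan)
    mean_fold = fold_sum / max(len(tumors), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2_fold_change"] = np.log2(mean_fold)
    out.loc[out["rpkm_normal"] == 0, "log2_fold_change"] = np.nan
    return out


def global_density_shift(
    normal: WindowedCountTrack,
    tumors: Sequence[WindowedCountTrack],
    bin_width: int = 5_000,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Genome fractions hypo-/hypermethylated from MeDIP density at coarse bins.

    Per-bin MeDIP density (count / library total) is compared tumor vs
    normal over bins with non-zero normal signal; a bin is hypomethylated
    if the ratio falls at or below 1/fold_threshold and hypermethylated at
    or above fold_threshold. Returns per-tumor fractions plus the mean.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    nb = _bin_counts(normal, "medip", bin_width)
    dens_n = nb["count"].to_numpy() / max(normal.medip_total, 1)
    nonempty = dens_n > 0
    rows = []
    for t in tumors:
        tb = _bin_counts(t, "medip", bin_width)
        dens_t = tb["count"].to_numpy() / max(t.medip_total, 1)
        ratio = dens_t[nonempty] / dens_n[nonempty]
        n = ratio.size
        rows.append({
            "sample": t.sample_id,
            "frac_hypo": float((ratio <= 1 / fold_threshold).sum() / n),
            "frac_hyper": float((ratio >= fold_threshold).sum() / n),
            "n_bins": n,
        })
    df = pd.DataFrame(rows)
    mean = {"sample": "mean", "frac_hypo": df["frac_hypo"].mean(),
            "frac_hyper": df["frac_hyper"].mean(), "n_bins": int(df["n_bins"].iloc[0])}
    return pd.concat([df, pd.DataFrame([mean])], ignore_index=True)
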