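"""Independent-cohort validation of DMRs on probe-array beta values.

A discovery panel of a few deeply profiled methylomes yields DMR
predictions; an independent cohort measured on an Infinium-style array
(beta values in [0, 1]) tests whether each DMR's methylation difference
recurs. Per DMR the average methylation level (aML) of its probes is
computed per sample group, the methylation change DMC = aML_cancer -
aML_normal, and a two-sided Mann-Whitney U test compares per-sample mean
betas between groups. After Benjamini-Hochberg correction a DMR is
validated iff q < 0.05, |DMC| > 0.05, and the observed direction matches
the discovery prediction.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import bh_adjust
from .genome import GenomicInterval

__all__ = [
    "BetaCohort",
    "ValidationRecord",
    "quantile_normalize",
    "probe_coverage",
    "probes_in_interval",
    "aml",
    "dmc",
    "mwu_test",
    "validate_dmrs",
]

EXACT_MWU_MAX_N = 12  # exact enumeration up to this combined sample size


@dataclass
class BetaCohort:
    """Probe manifest plus a probe x sample beta-value matrix with group labels."""

    manifest: pd.DataFrame  # columns: probe_id, chrom, position
    beta: pd.DataFrame      # index: probe_id, columns: sample ids, values in [0,1]/NaN
    groups: dict[str, str]  # sample id -> group label

    def __post_init__(self) -> None:
        needed = {"probe_id", "chrom", "position"}
        if not needed.issubset(self.manifest.columns):
            raise ValueError(f"manifest needs columns {sorted(needed)}")
        vals = self.beta.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        if not ok.all():
            raise ValueError("beta values must lie in [0, 1] (NaN allowed)")
        missing = [s for s in self.beta.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.manifest = self.manifest.sort_values(["chrom", "position"]).reset_index(drop=True)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.beta.columns if self.groups[s] == group]

    @classmethod
    def from_files(cls, manifest_path: str | os.PathLike, beta_path: str | os.PathLike,
                   groups_path: str | os.PathLike) -> "BetaCohort":
        manifest = pd.read_csv(manifest_path, sep="\t")
        beta = pd.read_csv(beta_path, sep="\t", index_col=0)
        gdf = pd.read_csv(groups_path, sep="\t")
        groups = dict(zip(gdf["sample"], gdf["group"]))
        return cls(manifest, beta, groups)

    def write(self, manifest_path, beta_path, groups_path) -> None:
        self.manifest.to_csv(manifest_path, sep="\t", index=False)
        self.beta.to_csv(beta_path, sep="\t", index_label="probe_id")
        pd.DataFrame(
            {"sample": list(self.beta.columns),
             "group": [self.groups[s] for s in self.beta.columns]}
        ).to_csv(groups_path, sep="\t", index=False)


@dataclass
class ValidationRecord:
    dmr: GenomicInterval
    w: int                       # probes inside the DMR
    aml_by_group: dict[str, float]
    dmc_value: float | None
    p_value: float | None
    q_value: float | None
    predicted_direction: str
    observed_direction: str | None
    validated: bool
    testable: bool


def quantile_normalize(beta: pd.DataFrame) -> pd.DataFrame:
    """Map each sample's sorted values onto the cross-sample mean quantile profile.

    Missing values stay missing and are excluded from rank computation;
    ties within a sample receive the average of their mapped values. With
    complete columns of equal length this is classic quantile
    normalization.
    """
    if beta.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    n_ref = int(beta.notna().sum().max())
    grid = (np.arange(n_ref) + 0.5) / n_ref
    # reference: average of per-sample quantile functions on a common grid
    profiles = []
    for col in beta.columns:
        v = np.sort(beta[col].dropna().to_numpy())
        if v.size == 0:
            continue
        qpos = (np.arange(v.size) + 0.5) / v.size
        profiles.append(np.interp(grid, qpos, v))
    reference = np.mean(profiles, axis=0)
    out = beta.copy()
    for col in beta.columns:
        mask = beta[col].notna().to_numpy()
        v = beta[col].to_numpy(dtype=float)[mask]
        if v.size == 0:
            continue
        ranks = stats.rankdata(v, method="average")  # tie-aware
        qpos = (ranks - 0.5) / v.size
        mapped = np.interp(qpos, grid, reference)
        new = out[col].to_numpy(dtype=float)
        new[mask] = mapped
        out[col] = new
    return out


def probes_in_interval(manifest: pd.DataFrame, iv: GenomicInterval) -> pd.DataFrame:
    """Probes whose position lies in ``[start, end)`` on the DMR's chromosome."""
    m = manifest
    return m[(m["chrom"] == iv.chrom) & (m["position"] >= iv.start) & (m["position"] < iv.end)]


def probe_coverage(
    dmrs_by_direction: Mapping[str, Sequence[GenomicInterval]],
    manifest: pd.DataFrame,
) -> pd.DataFrame:
    """Per direction class: fractions of DMRs with 0, >=1, >=2 and >2 probes."""
    rows = []
    for direction, dmrs in dmrs_by_direction.items():
        counts = np.array([len(probes_in_interval(manifest, d)) for d in dmrs])
        n = max(len(counts), 1)
        rows.append({
            "direction": direction,
            "n_dmrs": len(counts),
            "f0": float((counts == 0).sum() / n),
            "f_ge1": float((counts >= 1).sum() / n),
            "f_ge2": float((counts >= 2).sum() / n),
            "f_gt2": float((counts > 2).sum() / n),
        })
    return pd.DataFrame(rows)


def aml(block: pd.DataFrame | np.ndarray) -> float:
    """Average methylation level of a probe x sample beta block.

    Mean over all non-missing entries; NaN if every entry is missing.
    """
    vals = np.asarray(block, dtype=float).ravel()
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def dmc(aml_cancer: float, aml_normal: float) -> float:
    """DNA methylation change: aML_cancer - aML_normal."""
    return aml_cancer - aml_normal


def _mwu_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x vs y with 0.5 credit for ties."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mwu_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Combined sample sizes up to 12 are handled by exact enumeration of all
    group assignments of the pooled values (a permutation test on U, which
    is exact under ties as well); larger samples use the tie-corrected
    normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need >= 1 value")
    n, m = x.size, y.size
    if n + m <= EXACT_MWU_MAX_N:
        pooled = np.concatenate([x, y])
        u_obs = _mwu_u(x, y)
        center = n * m / 2.0
        dev = abs(u_obs - center) - 1e-9  # guard fp noise on the boundary
        hits = total = 0
        for idx in itertools.combinations(range(n + m), n):
            sel = np.zeros(n + m, dtype=bool)
            sel[list(idx)] = True
            u = _mwu_u(pooled[sel], pooled[~sel])
            total += 1
            if abs(u - center) >= dev:
                hits += 1
        return hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def validate_dmrs(
    dmrs: Sequence[GenomicInterval],
    cohort: BetaCohort,
    predictions: Sequence[str],
    cancer_group: str,
    normal_group: str,
    q_threshold: float = 0.05,
    dmc_threshold: float = 0.05,
    mode: str = "sample",
) -> list[ValidationRecord]:
    """Apply the three validation criteria to each DMR against the cohort.

    ``mode="sample"`` (default) feeds the Mann-Whitney test per-sample mean
    betas over the DMR's probes, so n equals the number of biological
    samples; ``mode="probe"`` pools probe-level values instead. DMRs with
    no probes, or without at least one non-missing value per group, are
    reported untestable and excluded from the BH family.
    """
    if mode not in {"sample", "probe"}:
        raise ValueError(f"unknown mode {mode!r}")
    for g in (cancer_group, normal_group):
        if not cohort.samples_in_group(g):
            raise ValueError(f"no samples in group {g!r}")
    cancer_samples = cohort.samples_in_group(cancer_group)
    normal_samples = cohort.samples_in_group(normal_group)

    records: list[ValidationRecord] = []
    p_list: list[float] = []
    testable_pos: list[int] = []
    for i, (iv, pred) in enumerate(zip(dmrs, predictions)):
        probes = probes_in_interval(cohort.manifest, iv)["probe_id"]
        w = len(probes)
        block = cohort.beta.loc[probes] if w else cohort.beta.iloc[0:0]
        aml_c = aml(block[cancer_samples]) if w else float("nan")
        aml_n = aml(block[normal_samples]) if w else float("nan")
        testable = w > 0 and not (np.isnan(aml_c) or np.isnan(aml_n))
        if testable:
            if mode == "sample":
                xs = block[cancer_samples].mean(axis=0, skipna=True).dropna().to_numpy()
                ys = block[normal_samples].mean(axis=0, skipna=True).dropna().to_numpy()
            else:
                xs = block[cancer_samples].to_numpy().ravel()
                xs = xs[~np.isnan(xs)]
                ys = block[normal_samples].to_numpy().ravel()
                ys = ys[~np.isnan(ys)]
            testable = xs.size >= 1 and ys.size >= 1
        rec = ValidationRecord(
            dmr=iv, w=w,
            aml_by_group={cancer_group: aml_c, normal_group: aml_n},
            dmc_value=dmc(aml_c, aml_n) if testable else None,
            p_value=None, q_value=None,
            predicted_direction=pred, observed_direction=None,
            validated=False, testable=testable,
        )
        if testable:
            rec.p_value = mwu_test(xs, ys)
            rec.observed_direction = "hyper" if rec.dmc_value > 0 else "hypo"
            p_list.append(rec.p_value)
            testable_pos.append(i)
        records.append(rec)

    if p_list:
        q = bh_adjust(p_list)
        for qi, pos in zip(q, testable_pos):
            rec = records[pos]
            rec.q_value = float(qi)
            rec.validated = (
                rec.q_value < q_threshold
                and abs(rec.dmc_value) > dmc_threshold
                and rec.observed_direction == rec.predicted_direction
            )
    return records


def validation_table(records: Sequence[ValidationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "chrom": r.dmr.chrom, "start": r.dmr.start, "end": r.dmr.end,
            "w": r.w, "dmc": r.dmc_value, "p_value": r.p_value, "q_value": r.q_value,
            "predicted": r.predicted_direction, "observed": r.observed_direction,
            "validated": r.validated, "testable": r.testable,
        })
    return pd.DataFrame(rows)
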