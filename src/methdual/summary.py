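"""Count summarization helpers shared by the pipeline and reports."""

from __future__ import annotations

from typing import Mapping, Sequence

from .calling import ConsensusDMR

__all__ = ["direction_fractions", "consensus_direction_counts", "class_summary"]


def direction_fractions(n_hyper: int, n_hypo: int) -> dict:
    """Total and direction percentages from hyper/hypo component counts.

    Percentages are rounded to the nearest whole percent, the convention
    used when reporting DMR direction splits.
    """
    total = n_hyper + n_hypo
    if total <= 0:
        return {"total": 0, "pct_hyper": 0.0, "pct_hypo": 0.0}
    return {
        "total": total,
        "pct_hyper": round(100.0 * n_hyper / total),
        "pct_hypo": round(100.0 * n_hypo / total),
    }


def consensus_direction_counts(dmrs: Sequence[ConsensusDMR]) -> dict:
    n_hyper = sum(d.direction == "hyper" for d in dmrs)
    n_hypo = len(dmrs) - n_hyper
    return {"n_hyper": n_hyper, "n_hypo": n_hypo, **direction_fractions(n_hyper, n_hypo)}


def class_summary(dmrs_by_class: Mapping[str, Sequence[ConsensusDMR]]) -> dict:
    return {label: consensus_direction_counts(dmrs) for label, dmrs in dmrs_by_class.items()}
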