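"""Quality filters applied before any sex-linkage scanning.

SNP loci are kept only at call rate = 1 and reproducibility = 1; the
presence/absence threshold is relaxed to call rate >= 0.90 (that file is
typically of slightly lower quality).  Filtering always uses the
DArT-reported metadata columns, never a recomputed non-null fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import PresenceMatrix, SnpMatrix

__all__ = ["FilterThresholds", "FilterReport", "filter_snp", "filter_pa"]


def _fraction(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return float(value)


@dataclass(frozen=True)
class FilterThresholds:
    """Per-file quality cut-offs.

    ``pa_call_rate_strict`` switches the presence/absence call-rate rule
    from ``>=`` (default) to strictly ``>``; retained loci in practice sit
    well above the 0.90 boundary either way.
    """

    snp_min_call_rate: float = 1.0
    snp_min_reproducibility: float = 1.0
    pa_min_call_rate: float = 0.90
    pa_min_reproducibility: float = 1.0
    pa_call_rate_strict: bool = False

    def __post_init__(self):
        for name in (
            "snp_min_call_rate",
            "snp_min_reproducibility",
            "pa_min_call_rate",
            "pa_min_reproducibility",
        ):
            object.__setattr__(self, name, _fraction(getattr(self, name), name))


@dataclass(frozen=True)
class FilterReport:
    stage: str
    input_loci: int
    retained_loci: int

    @property
    def dropped_loci(self) -> int:
        return self.input_loci - self.retained_loci

    def to_tsv_row(self) -> str:
        return f"{self.stage}\t{self.input_loci}\t{self.retained_loci}"


def filter_snp(
    matrix: SnpMatrix, thresholds: FilterThresholds | None = None
) -> tuple[SnpMatrix, FilterReport]:
    """Retain SNP loci meeting both thresholds (default: exactly 1.0 / 1.0).

    Sample set and locus order are preserved; an empty result is allowed.
    """
    t = thresholds or FilterThresholds()
    keep = (matrix.call_rate >= t.snp_min_call_rate) & (
        matrix.reproducibility >= t.snp_min_reproducibility
    )
    out = matrix.subset_loci(keep)
    return out, FilterReport("snp", matrix.n_loci, out.n_loci)


def filter_pa(
    matrix: PresenceMatrix, thresholds: FilterThresholds | None = None
) -> tuple[PresenceMatrix, FilterReport]:
    """Retain presence/absence loci at call rate >= 0.90, reproducibility = 1."""
    t = thresholds or FilterThresholds()
    if t.pa_call_rate_strict:
        rate_ok = matrix.call_rate > t.pa_min_call_rate
    else:
        rate_ok = matrix.call_rate >= t.pa_min_call_rate
    keep = rate_ok & (matrix.reproducibility >= t.pa_min_reproducibility)
    out = matrix.subset_loci(keep)
    return out, FilterReport("pa", matrix.n_loci, out.n_loci)


def write_filter_report(reports, path) -> None:
    """Filter report as a small TSV: stage, input_loci, retained_loci."""
    lines = ["stage\tinput_loci\tretained_loci"]
    lines += [r.to_tsv_row() for r in reports]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
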