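"""Per-locus sex-concordance scoring and heterogamety inference.

For each SNP locus and each heterogametic hypothesis (XY: males carry two
different sex chromosomes; ZW: females do) the score is

    S = (fraction of the heterogametic sex called heterozygous)
      + (fraction of the homogametic sex called homozygous reference)

with both fractions taken over *all* confidently sexed individuals of
that sex - null and discordant calls count against the proportion, they
are not removed from the denominator.  ``S = 2`` (both fractions exactly
1, checked on integer counts, never with a float tolerance) defines a
perfectly sex-linked locus.  Presence/absence loci are scored by the
fraction of the heterogametic sex with the fragment present and the
homogametic sex with it absent; a locus is sex-linked when both exceed a
threshold (default 0.90) and, optionally, no individual contradicts the
pattern outright (an absent call in the heterogametic sex or a present
call in the homogametic sex).

The spurious-linkage model prices the risk that a locus matches a
sex-specific pattern by chance: each individual matches with probability
0.5, so P_i = 0.5^n for n sexed individuals, and the expected number of
spuriously sex-linked loci among m tested is m * 0.5^n.  This assumes a
per-individual match probability of one half regardless of allele
frequency; the test suite checks it against a permutation oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .calls import PaCall, SnpCall
from .matrices import PresenceMatrix, SexRegistry, SnpMatrix

__all__ = [
    "System",
    "SnpLocusScore",
    "PaLocusScore",
    "SnpScan",
    "PaScan",
    "SpuriousEstimate",
    "LinkageReport",
    "score_snp_locus",
    "score_pa_locus",
    "scan_snp",
    "scan_pa",
    "find_moderate_loci",
    "infer_system",
    "spurious_probability",
    "expected_spurious",
    "min_sample_size",
]


class System(str, Enum):
    """Heterogametic system hypothesis (or inference outcome)."""

    XY = "XY"
    ZW = "ZW"
    UNDETERMINED = "UNDETERMINED"


def _as_system(system) -> System:
    s = System(system)
    if s is System.UNDETERMINED:
        raise ValueError("scoring requires a concrete hypothesis: XY or ZW")
    return s


def _sex_masks(sexes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sexes = np.asarray(sexes, dtype=object)
    males = sexes == "M"
    females = sexes == "F"
    if not males.any() or not females.any():
        raise ValueError(
            "score undefined: need at least one confidently sexed male "
            "and one female"
        )
    return males, females


def _het_hom_masks(sexes, system: System):
    males, females = _sex_masks(sexes)
    return (males, females) if system is System.XY else (females, males)


# ---------------------------------------------------------------------------
# per-locus scores


@dataclass(frozen=True)
class SnpLocusScore:
    locus_id: str
    system: System
    prop_het_heterogametic: float
    prop_homref_homogametic: float

    @property
    def score(self) -> float:
        return self.prop_het_heterogametic + self.prop_homref_homogametic

    @property
    def is_perfect(self) -> bool:
        return (
            self.prop_het_heterogametic == 1.0
            and self.prop_homref_homogametic == 1.0
        )


@dataclass(frozen=True)
class PaLocusScore:
    locus_id: str
    system: System
    prop_present_heterogametic: float
    prop_absent_homogametic: float
    prop_null_heterogametic: float
    prop_null_homogametic: float
    contradiction_free: bool


def score_snp_locus(calls, sexes, system="XY", locus_id: str = "") -> SnpLocusScore:
    """Score one SNP locus under one heterogametic hypothesis.

    ``calls`` and ``sexes`` are aligned per-sample vectors; unknown-sex
    (``U``) samples contribute to neither proportion.  Denominators are
    the full male (resp. female) counts.
    """
    system = _as_system(system)
    calls = np.asarray(calls, dtype=np.int8)
    het_mask, hom_mask = _het_hom_masks(np.asarray(sexes, dtype=object), system)
    prop_het = float(np.count_nonzero(calls[het_mask] == SnpCall.HET)) / int(
        het_mask.sum()
    )
    prop_hom = float(np.count_nonzero(calls[hom_mask] == SnpCall.HOM_REF)) / int(
        hom_mask.sum()
    )
    return SnpLocusScore(locus_id, system, prop_het, prop_hom)


def score_pa_locus(calls, sexes, system="XY", locus_id: str = "") -> PaLocusScore:
    """Score one presence/absence locus under one hypothesis."""
    system = _as_system(system)
    calls = np.asarray(calls, dtype=np.int8)
    het_mask, hom_mask = _het_hom_masks(np.asarray(sexes, dtype=object), system)
    n_het, n_hom = int(het_mask.sum()), int(hom_mask.sum())
    het_calls, hom_calls = calls[het_mask], calls[hom_mask]
    return PaLocusScore(
        locus_id,
        system,
        prop_present_heterogametic=np.count_nonzero(het_calls == PaCall.PRESENT) / n_het,
        prop_absent_homogametic=np.count_nonzero(hom_calls == PaCall.ABSENT) / n_hom,
        prop_null_heterogametic=np.count_nonzero(het_calls == PaCall.NULL) / n_het,
        prop_null_homogametic=np.count_nonzero(hom_calls == PaCall.NULL) / n_hom,
        contradiction_free=(
            not np.any(het_calls == PaCall.ABSENT)
            and not np.any(hom_calls == PaCall.PRESENT)
        ),
    )


# ---------------------------------------------------------------------------
# whole-matrix scans


@dataclass
class SnpScan:
    """Both hypotheses' score tables plus the perfectly linked loci."""

    xy: pd.DataFrame
    zw: pd.DataFrame
    perfect_xy: list[str]
    perfect_zw: list[str]

    def scores(self, system) -> pd.DataFrame:
        return self.xy if System(system) is System.XY else self.zw

    def perfect(self, system) -> list[str]:
        return self.perfect_xy if System(system) is System.XY else self.perfect_zw


@dataclass
class PaScan:
    xy: pd.DataFrame
    zw: pd.DataFrame
    linked_xy: list[str]
    linked_zw: list[str]

    def scores(self, system) -> pd.DataFrame:
        return self.xy if System(system) is System.XY else self.zw

    def linked(self, system) -> list[str]:
        return self.linked_xy if System(system) is System.XY else self.linked_zw


def _snp_score_table(matrix, het_mask, hom_mask, system: System) -> tuple[pd.DataFrame, np.ndarray]:
    n_het, n_hom = int(het_mask.sum()), int(hom_mask.sum())
    het_counts = np.count_nonzero(matrix.calls[:, het_mask] == SnpCall.HET, axis=1)
    hom_counts = np.count_nonzero(matrix.calls[:, hom_mask] == SnpCall.HOM_REF, axis=1)
    perfect = (het_counts == n_het) & (hom_counts == n_hom)
    table = pd.DataFrame(
        {
            "locus_id": matrix.locus_ids,
            "system": system.value,
            "prop_het_heterogametic": het_counts / n_het,
            "prop_homref_homogametic": hom_counts / n_hom,
        }
    )
    table["score"] = table["prop_het_heterogametic"] + table["prop_homref_homogametic"]
    table["perfect"] = perfect
    return table, perfect


def scan_snp(matrix: SnpMatrix, registry: SexRegistry) -> SnpScan:
    """Score every SNP locus under both hypotheses.

    Deterministic; list order follows input locus order.  Perfect lists
    contain exactly the loci with S = 2 (integer-exact).
    """
    sexes = registry.sexes_for(matrix.sample_ids)
    males, females = _sex_masks(sexes)
    xy, perf_xy = _snp_score_table(matrix, males, females, System.XY)
    zw, perf_zw = _snp_score_table(matrix, females, males, System.ZW)
    return SnpScan(
        xy=xy,
        zw=zw,
        perfect_xy=list(matrix.locus_ids[perf_xy]),
        perfect_zw=list(matrix.locus_ids[perf_zw]),
    )


def _pa_score_table(matrix, het_mask, hom_mask, system, min_prop, require_cf):
    n_het, n_hom = int(het_mask.sum()), int(hom_mask.sum())
    het = matrix.calls[:, het_mask]
    hom = matrix.calls[:, hom_mask]
    present_het = np.count_nonzero(het == PaCall.PRESENT, axis=1)
    absent_hom = np.count_nonzero(hom == PaCall.ABSENT, axis=1)
    cf = ~np.any(het == PaCall.ABSENT, axis=1) & ~np.any(hom == PaCall.PRESENT, axis=1)
    table = pd.DataFrame(
        {
            "locus_id": matrix.locus_ids,
            "system": system.value,
            "prop_present_heterogametic": present_het / n_het,
            "prop_absent_homogametic": absent_hom / n_hom,
            "prop_null_heterogametic": np.count_nonzero(het == PaCall.NULL, axis=1) / n_het,
            "prop_null_homogametic": np.count_nonzero(hom == PaCall.NULL, axis=1) / n_hom,
            "contradiction_free": cf,
        }
    )
    linked = (
        (table["prop_present_heterogametic"] >= min_prop)
        & (table["prop_absent_homogametic"] >= min_prop)
    ).to_numpy()
    if require_cf:
        linked &= cf
    table["linked"] = linked
    return table, linked


def scan_pa(
    matrix: PresenceMatrix,
    registry: SexRegistry,
    min_prop: float = 0.9,
    require_contradiction_free: bool = True,
) -> PaScan:
    """Identify sex-linked presence/absence loci under both hypotheses."""
    sexes = registry.sexes_for(matrix.sample_ids)
    males, females = _sex_masks(sexes)
    xy, linked_xy = _pa_score_table(
        matrix, males, females, System.XY, min_prop, require_contradiction_free
    )
    zw, linked_zw = _pa_score_table(
        matrix, females, males, System.ZW, min_prop, require_contradiction_free
    )
    return PaScan(
        xy=xy,
        zw=zw,
        linked_xy=list(matrix.locus_ids[linked_xy]),
        linked_zw=list(matrix.locus_ids[linked_zw]),
    )


def find_moderate_loci(
    matrix: SnpMatrix,
    registry: SexRegistry,
    system="XY",
    min_het_prop: float = 0.25,
    perfect_loci=(),
    allow_null_homogametic: bool = False,
) -> list[str]:
    """Moderately sex-linked loci: homogametic sex all homozygous reference,
    heterogametic-sex heterozygosity in ``[min_het_prop, 1)``.

    The registry may carry genotypic assignments for formerly unknown-sex
    samples (see :func:`dartsex.sexing.assign_sex`); the perfect list is
    always excluded.  By default a null call in the homogametic sex
    disqualifies the locus.
    """
    system = _as_system(system)
    sexes = registry.sexes_for(matrix.sample_ids)
    het_mask, hom_mask = _het_hom_masks(sexes, system)
    n_het = int(het_mask.sum())
    hom = matrix.calls[:, hom_mask]
    if allow_null_homogametic:
        hom_ok = np.all((hom == SnpCall.HOM_REF) | (hom == SnpCall.NULL), axis=1)
    else:
        hom_ok = np.all(hom == SnpCall.HOM_REF, axis=1)
    het_counts = np.count_nonzero(matrix.calls[:, het_mask] == SnpCall.HET, axis=1)
    mask = hom_ok & (het_counts >= min_het_prop * n_het) & (het_counts < n_het)
    excluded = set(perfect_loci)
    return [x for x in matrix.locus_ids[mask] if x not in excluded]


# ---------------------------------------------------------------------------
# system inference and the spurious-linkage model


def infer_system(
    perfect_xy: int, perfect_zw: int, pa_xy: int = 0, pa_zw: int = 0
) -> System:
    """Infer the heterogametic system from marker counts.

    Strictly exclusive: any conflicting evidence (or none at all) yields
    UNDETERMINED rather than a majority vote.
    """
    xy_evidence = perfect_xy + pa_xy
    zw_evidence = perfect_zw + pa_zw
    if xy_evidence > 0 and zw_evidence == 0:
        return System.XY
    if zw_evidence > 0 and xy_evidence == 0:
        return System.ZW
    return System.UNDETERMINED


def spurious_probability(n: int) -> float:
    """P that one locus matches a sex-specific pattern by chance: 0.5**n."""
    if int(n) != n or n < 1:
        raise ValueError("n must be a positive integer")
    return 0.5 ** int(n)


def expected_spurious(m: int, n: int) -> float:
    """Expected count of spuriously sex-linked loci among m tested: m * 0.5**n."""
    if m < 0:
        raise ValueError("m must be nonnegative")
    if m == 0:
        return 0.0
    return m * spurious_probability(n)


def min_sample_size(m: int, max_expected: float = 1.0) -> int:
    """Smallest n with ``m * 0.5**n < max_expected`` (strict inequality)."""
    if m < 1:
        raise ValueError("m must be a positive integer")
    if max_expected <= 0:
        raise ValueError("max_expected must be positive")
    # ceil of log2(m / max_expected), then adjust for strictness
    n = max(1, math.ceil(math.log2(m / max_expected)))
    while expected_spurious(m, n) >= max_expected:
        n += 1
    while n > 1 and expected_spurious(m, n - 1) < max_expected:
        n -= 1
    return n


@dataclass(frozen=True)
class SpuriousEstimate:
    """The 0.5**n spurious-linkage budget for one marker class."""

    n: int
    m: int

    @property
    def p_per_locus(self) -> float:
        return spurious_probability(self.n)

    @property
    def expected_spurious(self) -> float:
        return expected_spurious(self.m, self.n)


# ---------------------------------------------------------------------------
# combined report


@dataclass
class LinkageReport:
    """Everything the discovery scan produced, for one data set."""

    inferred_system: System
    perfect_snp_loci: list[str] = field(default_factory=list)
    moderate_snp_loci: list[str] = field(default_factory=list)
    pa_linked_loci: list[str] = field(default_factory=list)
    snp_scan: SnpScan | None = None
    pa_scan: PaScan | None = None
    spurious: dict[str, SpuriousEstimate] = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.perfect_snp_loci) & set(self.moderate_snp_loci)
        if overlap:
            raise ValueError(f"loci classified both perfect and moderate: {sorted(overlap)}")

    def snp_locus_table(self) -> pd.DataFrame:
        """Long-format per-locus table (one row per locus and system)."""
        if self.snp_scan is None:
            return pd.DataFrame()
        table = pd.concat([self.snp_scan.xy, self.snp_scan.zw], ignore_index=True)
        perfect = set(self.perfect_snp_loci)
        moderate = set(self.moderate_snp_loci)
        sys_val = self.inferred_system.value

        def classify(row):
            if row["perfect"]:
                return "perfect"
            if row["system"] == sys_val and row["locus_id"] in moderate:
                return "moderate"
            return "unlinked"

        table["classification"] = table.apply(classify, axis=1)
        return table.drop(columns=["perfect"])

    def pa_locus_table(self) -> pd.DataFrame:
        if self.pa_scan is None:
            return pd.DataFrame()
        table = pd.concat([self.pa_scan.xy, self.pa_scan.zw], ignore_index=True)
        table["classification"] = np.where(table["linked"], "pa_linked", "unlinked")
        return table.drop(columns=["linked"])
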