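"""Male heterozygosity profiling over moderately sex-linked loci.

Each male's heterozygous fraction across the moderate loci places him in
one of three Y-lineage groups: fully heterozygous (Males 1, a fraction of
exactly 1), highly heterozygous (Males 2, >= 85% by default) and the
"feminised-Y" low-heterozygosity group (Males 3, <= 20%).  Fractions use
non-null calls as the denominator - grouping is per individual and a null
carries no genotype (unlike the discovery scan's all-individuals
denominator, which mirrors the marker-level concordance construction).

Groups 2 and 3 are compared with a Welch two-sample t-test (unequal
variances, Welch-Satterthwaite degrees of freedom, two-tailed p).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .calls import SnpCall
from .matrices import SnpMatrix

__all__ = [
    "MaleHetProfile",
    "Group",
    "GroupAssignment",
    "WelchResult",
    "male_het_profiles",
    "assign_groups",
    "welch_t_from_values",
    "welch_t_from_summary",
]


class Group(str, Enum):
    MALES1 = "MALES1"
    MALES2 = "MALES2"
    MALES3 = "MALES3"
    UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class MaleHetProfile:
    sample_id: str
    n_loci: int  # moderate loci with a non-null call for this male
    het_fraction: float  # HET / n_loci; nan when n_loci == 0

    @property
    def defined(self) -> bool:
        return self.n_loci > 0


def male_het_profiles(
    matrix: SnpMatrix,
    moderate_loci,
    males,
    *,
    denominator: str = "called",
) -> list[MaleHetProfile]:
    """Per-male heterozygous fraction over the moderate loci.

    ``denominator='called'`` (default) uses the male's non-null calls;
    ``'all'`` divides by the full locus count, nulls counting against.
    Homozygous-reference and homozygous-alternate calls both count as
    non-heterozygous.  A male with no non-null call gets an undefined
    (nan) profile and is excluded from grouping.
    """
    if denominator not in ("called", "all"):
        raise ValueError("denominator must be 'called' or 'all'")
    moderate_loci = list(moderate_loci)
    locus_idx = np.array([matrix.locus_index(x) for x in moderate_loci], dtype=int)
    profiles = []
    for sample in males:
        col = matrix.calls[locus_idx, matrix.sample_index(sample)]
        called = int(np.count_nonzero(col != SnpCall.NULL))
        het = int(np.count_nonzero(col == SnpCall.HET))
        if denominator == "all":
            n = len(moderate_loci)
        else:
            n = called
        frac = het / n if n > 0 else float("nan")
        profiles.append(MaleHetProfile(sample, called, frac))
    return profiles


@dataclass
class GroupAssignment:
    """Assignment of each profiled male to a lineage group."""

    assignments: dict[str, Group]
    high: float
    low: float

    def members(self, group: Group) -> list[str]:
        return [s for s, g in self.assignments.items() if g is group]

    @property
    def counts(self) -> dict[Group, int]:
        out = {g: 0 for g in Group}
        for g in self.assignments.values():
            out[g] += 1
        return out

    def to_frame(self, profiles) -> pd.DataFrame:
        rows = []
        for p in profiles:
            group = self.assignments.get(p.sample_id)
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "n_loci": p.n_loci,
                    "het_fraction": p.het_fraction,
                    "group": group.value if group else "UNDEFINED",
                }
            )
        return pd.DataFrame(rows)


def assign_groups(profiles, high: float = 0.85, low: float = 0.20) -> GroupAssignment:
    """Threshold rule: MALES1 iff fraction = 1; MALES2 iff high <= f < 1;
    MALES3 iff f <= low; otherwise UNASSIGNED.  Undefined profiles are
    skipped entirely."""
    assignments: dict[str, Group] = {}
    for p in profiles:
        if not p.defined or not np.isfinite(p.het_fraction):
            continue
        f = p.het_fraction
        if f == 1.0:
            g = Group.MALES1
        elif high <= f < 1.0:
            g = Group.MALES2
        elif f <= low:
            g = Group.MALES3
        else:
            g = Group.UNASSIGNED
        assignments[p.sample_id] = g
    return GroupAssignment(assignments, high=high, low=low)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float  # Welch-Satterthwaite, real-valued
    p_two_tailed: float
    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float

    @property
    def df_floor(self) -> int:
        """Integer degrees of freedom as conventionally printed, t(df)."""
        return int(np.floor(self.df))


def welch_t_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> WelchResult:
    """Welch t-test from group summaries (n, mean, sample sd with n-1)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    se2 = v1 + v2
    if se2 == 0.0:
        if mean1 == mean2:
            raise ValueError("t undefined: zero variance in both groups, equal means")
        t = np.inf if mean1 > mean2 else -np.inf
        return WelchResult(float(t), float("nan"), 0.0, n1, mean1, sd1, n2, mean2, sd2)
    t = (mean1 - mean2) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p), n1, mean1, sd1, n2, mean2, sd2)


def welch_t_from_values(a, b) -> WelchResult:
    """Welch t-test from raw observations (two-tailed)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    return welch_t_from_summary(
        a.size, float(a.mean()), float(a.std(ddof=1)),
        b.size, float(b.mean()), float(b.std(ddof=1)),
    )
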