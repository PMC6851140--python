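"""Synthetic DArTseq-style data with planted sex-linked structure.

The generator emulates a population genotyped for SNP and
presence/absence markers under a male-heterogametic (XY) system:

* perfectly sex-linked SNP loci - every true male heterozygous, every
  true female homozygous reference;
* moderately sex-linked SNP loci - females homozygous reference, males
  heterozygous with a lineage-specific probability.  Three male
  lineages model a fully heterozygous Y, a high-heterozygosity
  (recombining, pseudoautosomal) Y and a low-heterozygosity
  "feminised" Y;
* Y-specific presence/absence fragments - present in males, absent in
  females;
* autosomal SNP and PA loci at Hardy-Weinberg proportions with
  per-locus allele frequencies drawn uniformly from ``freq_range``.

Autosomal loci are drawn *conditional on not matching a sex-linked
pattern* (under either XY or ZW, with respect to the true sexes), so
the emitted truth labels are exactly consistent with the matrices at
zero noise; :func:`hardy_weinberg_snp` provides the unconditioned
generator for Monte-Carlo null studies.  Similarly, each male's
moderate-locus heterozygosity vector is redrawn until his realised
fraction lies inside his lineage's band (1.0 exactly; [high, 1); or
(0, low]), so the planted lineage structure is recoverable from a
single realisation while per-locus calls remain Bernoulli with the
lineage probability.

A fraction of samples can have the phenotype masked to unknown (``U``)
or flipped relative to the genotype (sex reversal); genotypes always
follow the true sex.  All output is bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .calls import PaCall, SnpCall
from .io import write_pa_table, write_sex_registry, write_snp_table
from .matrices import PresenceMatrix, SexRegistry, SnpMatrix

__all__ = [
    "SimParams",
    "SimTruth",
    "SimResult",
    "simulate",
    "study_preset",
    "hardy_weinberg_snp",
    "write_simulation",
]

# locus truth classes
PERFECT_SNP = "PERFECT_SNP"
MODERATE_SNP = "MODERATE_SNP"
AUTOSOMAL_SNP = "AUTOSOMAL_SNP"
PA_LINKED = "PA_LINKED"
AUTOSOMAL_PA = "AUTOSOMAL_PA"


@dataclass(frozen=True)
class SimParams:
    """Generator settings.  Defaults mirror the 52-frog study population:
    34 true males in lineages of 13/12/9, 18 true females, 8 phenotypes
    masked unknown, 11 perfect + 47 moderate SNP loci, 6 Y-specific PA
    fragments, and autosomal counts chosen so the filtered matrices hold
    20,111 SNP and 19,121 PA loci."""

    n_females: int = 18
    n_males1: int = 13
    n_males2: int = 12
    n_males3: int = 9
    n_unknown: int = 8
    n_perfect_loci: int = 11
    n_moderate_loci: int = 47
    n_pa_loci: int = 6
    n_autosomal_snp: int = 20053
    n_autosomal_pa: int = 19115
    p_het_lineage: tuple[float, float, float] = (1.0, 0.92, 0.16)
    freq_range: tuple[float, float] = (0.05, 0.95)
    null_rate: float = 0.0
    callrate_noise: float = 0.0
    n_sex_reversed: int = 0
    n_sites: int = 3
    seed: int = 2019
    # bands used both to constrain lineage heterozygosity and to screen
    # autosomal loci against chance sex-linked patterns
    group_high: float = 0.85
    group_low: float = 0.20
    min_het_prop_guard: float = 0.25
    pa_min_prop_guard: float = 0.90
    exclude_spurious_autosomal: bool = True

    def validate(self) -> None:
        counts = {
            "n_females": self.n_females,
            "n_males1": self.n_males1,
            "n_males2": self.n_males2,
            "n_males3": self.n_males3,
            "n_unknown": self.n_unknown,
            "n_perfect_loci": self.n_perfect_loci,
            "n_moderate_loci": self.n_moderate_loci,
            "n_pa_loci": self.n_pa_loci,
            "n_autosomal_snp": self.n_autosomal_snp,
            "n_autosomal_pa": self.n_autosomal_pa,
            "n_sex_reversed": self.n_sex_reversed,
        }
        for name, value in counts.items():
            if value < 0 or int(value) != value:
                raise ValueError(f"{name} must be a nonnegative integer")
        for name in ("null_rate", "callrate_noise"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for p in self.p_het_lineage:
            if not 0.0 <= p <= 1.0:
                raise ValueError("lineage het probabilities must lie in [0, 1]")
        lo, hi = self.freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("freq_range must satisfy 0 < lo <= hi < 1")
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        if self.n_males == 0 and (
            self.n_perfect_loci or self.n_moderate_loci or self.n_pa_loci
        ):
            raise ValueError("sex-linked loci require at least one male")
        if self.n_females == 0 and (
            self.n_perfect_loci or self.n_moderate_loci or self.n_pa_loci
        ):
            raise ValueError("sex-linked loci require at least one female")
        if self.n_unknown + self.n_sex_reversed > self.n_samples:
            raise ValueError("more masked/reversed samples than samples")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    @property
    def n_males(self) -> int:
        return self.n_males1 + self.n_males2 + self.n_males3

    @property
    def n_samples(self) -> int:
        return self.n_females + self.n_males


def study_preset(seed: int | None = None) -> SimParams:
    """The study-population parameter set (optionally reseeded)."""
    params = SimParams()
    return params if seed is None else replace(params, seed=int(seed))


@dataclass
class SimTruth:
    """Ground truth behind one simulated data set."""

    samples: pd.DataFrame  # sample_id, true_sex, phenotype, lineage, site
    snp_classes: pd.DataFrame  # locus_id, locus_class
    pa_classes: pd.DataFrame

    def loci_of(self, locus_class: str) -> list[str]:
        for table in (self.snp_classes, self.pa_classes):
            hit = table[table["locus_class"] == locus_class]
            if len(hit):
                return list(hit["locus_id"])
        return []

    def true_registry(self) -> SexRegistry:
        """Registry of the *true* sexes (as if every phenotype were known)."""
        return SexRegistry(
            dict(zip(self.samples["sample_id"], self.samples["true_sex"])),
            dict(zip(self.samples["sample_id"], self.samples["site"])),
        )

    @property
    def sex_reversed(self) -> list[str]:
        mask = (
            self.samples["phenotype"].isin(["M", "F"])
            & (self.samples["phenotype"] != self.samples["true_sex"])
        )
        return list(self.samples.loc[mask, "sample_id"])

    def lineage_members(self, lineage: int) -> list[str]:
        hit = self.samples[self.samples["lineage"] == lineage]
        return list(hit["sample_id"])

    def write_tsv(self, path) -> None:
        rows = self.samples.assign(kind="sample", locus_class="")
        snp = self.snp_classes.assign(kind="snp_locus")
        pa = self.pa_classes.assign(kind="pa_locus")
        loci = pd.concat([snp, pa], ignore_index=True).rename(
            columns={"locus_id": "sample_id"}
        )
        loci = loci.assign(true_sex="", phenotype="", lineage="", site="")
        table = pd.concat([rows, loci], ignore_index=True)[
            ["kind", "sample_id", "true_sex", "phenotype", "lineage", "site", "locus_class"]
        ].rename(columns={"sample_id": "id"})
        table.to_csv(path, sep="\t", index=False)


@dataclass
class SimResult:
    snp: SnpMatrix
    pa: PresenceMatrix
    registry: SexRegistry
    truth: SimTruth


# ---------------------------------------------------------------------------
# building blocks


def hardy_weinberg_snp(
    rng: np.random.Generator,
    n_loci: int,
    n_samples: int,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> tuple[np.ndarray, np.ndarray]:
    """Unconditioned Hardy-Weinberg SNP calls.

    Returns ``(calls, freqs)`` where ``calls`` is (n_loci, n_samples) of
    :class:`SnpCall` codes and ``freqs`` the reference-allele frequency
    drawn uniformly from ``freq_range`` per locus.
    """
    freqs = rng.uniform(freq_range[0], freq_range[1], size=n_loci)
    u = rng.random((n_loci, n_samples))
    p2 = (freqs**2)[:, None]
    het_cut = p2 + (2 * freqs * (1 - freqs))[:, None]
    calls = np.full((n_loci, n_samples), int(SnpCall.HOM_ALT), dtype=np.int8)
    calls[u < het_cut] = SnpCall.HET
    calls[u < p2] = SnpCall.HOM_REF
    return calls, freqs


def _sexlinked_snp_pattern(calls, male_idx, female_idx, guard) -> np.ndarray:
    """Loci matching a perfect or moderate sex-linked pattern, either system."""
    males = calls[:, male_idx]
    females = calls[:, female_idx]
    n_m, n_f = len(male_idx), len(female_idx)
    m_het = np.count_nonzero(males == SnpCall.HET, axis=1)
    f_het = np.count_nonzero(females == SnpCall.HET, axis=1)
    xy_like = np.all(females == SnpCall.HOM_REF, axis=1) & (m_het >= guard * n_m)
    zw_like = np.all(males == SnpCall.HOM_REF, axis=1) & (f_het >= guard * n_f)
    return xy_like | zw_like


def _sexlinked_pa_pattern(calls, male_idx, female_idx, min_prop) -> np.ndarray:
    males = calls[:, male_idx]
    females = calls[:, female_idx]
    n_m, n_f = len(male_idx), len(female_idx)
    pres_m = np.count_nonzero(males == PaCall.PRESENT, axis=1)
    abs_f = np.count_nonzero(females == PaCall.ABSENT, axis=1)
    pres_f = np.count_nonzero(females == PaCall.PRESENT, axis=1)
    abs_m = np.count_nonzero(males == PaCall.ABSENT, axis=1)
    xy_like = (
        (pres_m >= min_prop * n_m)
        & (abs_f >= min_prop * n_f)
        & (abs_m == 0)
        & (pres_f == 0)
    )
    zw_like = (
        (pres_f >= min_prop * n_f)
        & (abs_m >= min_prop * n_m)
        & (abs_f == 0)
        & (pres_m == 0)
    )
    return xy_like | zw_like


def _lineage_band(p: float, high: float, low: float) -> tuple[int, int] | None:
    """Admissible het-count band (inclusive, as fractions of n) for a male
    whose lineage heterozygosity is ``p``; None when unconstrained."""
    if p == 1.0:
        return ("exact_one", None)
    if high <= p < 1.0:
        return ("high", None)
    if 0.0 < p <= low:
        return ("low", None)
    return None


def _draw_moderate_column(rng, n_loci, p, band, high, low, max_tries=10_000):
    """Bernoulli(p) het vector conditioned on the lineage band."""
    if n_loci == 0:
        return np.zeros(0, dtype=bool)
    if p == 1.0:
        return np.ones(n_loci, dtype=bool)
    if p == 0.0:
        return np.zeros(n_loci, dtype=bool)
    for _ in range(max_tries):
        het = rng.random(n_loci) < p
        if band is None:
            return het
        frac = het.mean()
        kind = band[0]
        if kind == "exact_one" and frac == 1.0:
            return het
        if kind == "high" and high <= frac < 1.0:
            return het
        if kind == "low" and 0.0 < frac <= low:
            return het
    raise RuntimeError(
        f"could not draw a lineage-consistent heterozygosity vector "
        f"(p={p}, band={band}); check p_het_lineage against the group thresholds"
    )


# ---------------------------------------------------------------------------
# the generator


def simulate(params: SimParams | None = None) -> SimResult:
    """Generate (SnpMatrix, PresenceMatrix, SexRegistry, SimTruth)."""
    params = params or SimParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    # -- samples -------------------------------------------------------------
    n = params.n_samples
    width = max(2, len(str(n)))
    sample_ids = [f"ind{i + 1:0{width}d}" for i in range(n)]
    true_sex = np.array(
        ["F"] * params.n_females + ["M"] * params.n_males, dtype=object
    )
    lineage = np.zeros(n, dtype=int)
    start = params.n_females
    for k, size in enumerate(
        (params.n_males1, params.n_males2, params.n_males3), start=1
    ):
        lineage[start : start + size] = k
        start += size
    female_idx = np.nonzero(true_sex == "F")[0]
    male_idx = np.nonzero(true_sex == "M")[0]

    site_labels = np.array(
        [f"site{(i % params.n_sites) + 1}" for i in range(n)], dtype=object
    )
    site_labels = site_labels[rng.permutation(n)]

    phenotype = true_sex.copy()
    masked = rng.choice(n, size=params.n_unknown, replace=False)
    phenotype[masked] = "U"
    if params.n_sex_reversed:
        eligible = np.setdiff1d(np.arange(n), masked)
        reversed_idx = rng.choice(eligible, size=params.n_sex_reversed, replace=False)
        flip = {"M": "F", "F": "M"}
        for i in reversed_idx:
            phenotype[i] = flip[true_sex[i]]

    # -- SNP loci ------------------------------------------------------------
    def _ids(prefix, count):
        w = max(2, len(str(count)))
        return [f"{prefix}{i + 1:0{w}d}" for i in range(count)]

    perfect_ids = _ids("SNPperf", params.n_perfect_loci)
    moderate_ids = _ids("SNPmod", params.n_moderate_loci)
    auto_snp_ids = _ids("SNPauto", params.n_autosomal_snp)

    perfect = np.full((params.n_perfect_loci, n), int(SnpCall.HOM_REF), dtype=np.int8)
    perfect[:, male_idx] = SnpCall.HET

    # a locus that happened to be heterozygous in *every* male would be
    # indistinguishable from a perfect locus, contradicting its truth
    # label; redraw the block until none is (impossible when every
    # lineage is fully heterozygous, in which case the loci legitimately
    # degenerate to perfect ones)
    lineages_present = {lineage[i] for i in male_idx}
    can_be_partial = any(
        params.p_het_lineage[k - 1] < 1.0 for k in lineages_present
    )
    for _ in range(200):
        moderate = np.full(
            (params.n_moderate_loci, n), int(SnpCall.HOM_REF), dtype=np.int8
        )
        for i in male_idx:
            p = params.p_het_lineage[lineage[i] - 1]
            band = _lineage_band(p, params.group_high, params.group_low)
            het = _draw_moderate_column(
                rng, params.n_moderate_loci, p, band, params.group_high, params.group_low
            )
            moderate[het, i] = SnpCall.HET
        if not can_be_partial or params.n_moderate_loci == 0 or not len(male_idx):
            break
        all_het = np.all(moderate[:, male_idx] == SnpCall.HET, axis=1)
        if not all_het.any():
            break
    else:  # pragma: no cover - needs pathological lineage probabilities
        raise RuntimeError("could not draw truth-consistent moderate loci")

    auto_snp, _ = hardy_weinberg_snp(
        rng, params.n_autosomal_snp, n, params.freq_range
    )
    if (
        params.exclude_spurious_autosomal
        and params.n_autosomal_snp
        and len(male_idx)
        and len(female_idx)
    ):
        for _ in range(100):
            bad = _sexlinked_snp_pattern(
                auto_snp, male_idx, female_idx, params.min_het_prop_guard
            )
            if not bad.any():
                break
            redraw, _ = hardy_weinberg_snp(
                rng, int(bad.sum()), n, params.freq_range
            )
            auto_snp[bad] = redraw
        else:  # pragma: no cover - would need pathological parameters
            raise RuntimeError("could not draw pattern-free autosomal SNP loci")

    snp_calls = np.vstack([perfect, moderate, auto_snp]).astype(np.int8)
    snp_ids = perfect_ids + moderate_ids + auto_snp_ids

    # -- PA loci -------------------------------------------------------------
    pa_link_ids = _ids("PAlink", params.n_pa_loci)
    auto_pa_ids = _ids("PAauto", params.n_autosomal_pa)

    pa_linked = np.full((params.n_pa_loci, n), int(PaCall.ABSENT), dtype=np.int8)
    pa_linked[:, male_idx] = PaCall.PRESENT

    freq = rng.uniform(*params.freq_range, size=params.n_autosomal_pa)
    auto_pa = np.where(
        rng.random((params.n_autosomal_pa, n)) < freq[:, None],
        int(PaCall.PRESENT),
        int(PaCall.ABSENT),
    ).astype(np.int8)
    if (
        params.exclude_spurious_autosomal
        and params.n_autosomal_pa
        and len(male_idx)
        and len(female_idx)
    ):
        for _ in range(100):
            bad = _sexlinked_pa_pattern(
                auto_pa, male_idx, female_idx, params.pa_min_prop_guard
            )
            if not bad.any():
                break
            f2 = rng.uniform(*params.freq_range, size=int(bad.sum()))
            auto_pa[bad] = np.where(
                rng.random((int(bad.sum()), n)) < f2[:, None],
                int(PaCall.PRESENT),
                int(PaCall.ABSENT),
            ).astype(np.int8)
        else:  # pragma: no cover
            raise RuntimeError("could not draw pattern-free autosomal PA loci")

    pa_calls = np.vstack([pa_linked, auto_pa]).astype(np.int8)
    pa_ids = pa_link_ids + auto_pa_ids

    # -- noise ---------------------------------------------------------------
    if params.null_rate > 0:
        snp_calls[rng.random(snp_calls.shape) < params.null_rate] = SnpCall.NULL
        pa_calls[rng.random(pa_calls.shape) < params.null_rate] = PaCall.NULL

    def _metadata(n_loci):
        rate = np.ones(n_loci)
        if params.callrate_noise > 0:
            noisy = rng.random(n_loci) < params.callrate_noise
            rate[noisy] = rng.uniform(0.5, 1.0, size=int(noisy.sum()))
        return rate, np.ones(n_loci)

    snp_rate, snp_rep = _metadata(len(snp_ids))
    pa_rate, pa_rep = _metadata(len(pa_ids))

    snp = SnpMatrix(
        snp_ids, sample_ids, snp_calls, call_rate=snp_rate, reproducibility=snp_rep
    )
    pa = PresenceMatrix(
        pa_ids, sample_ids, pa_calls, call_rate=pa_rate, reproducibility=pa_rep
    )
    registry = SexRegistry(
        dict(zip(sample_ids, phenotype)), dict(zip(sample_ids, site_labels))
    )

    truth = SimTruth(
        samples=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "true_sex": true_sex,
                "phenotype": phenotype,
                "lineage": lineage,
                "site": site_labels,
            }
        ),
        snp_classes=pd.DataFrame(
            {
                "locus_id": snp_ids,
                "locus_class": [PERFECT_SNP] * len(perfect_ids)
                + [MODERATE_SNP] * len(moderate_ids)
                + [AUTOSOMAL_SNP] * len(auto_snp_ids),
            }
        ),
        pa_classes=pd.DataFrame(
            {
                "locus_id": pa_ids,
                "locus_class": [PA_LINKED] * len(pa_link_ids)
                + [AUTOSOMAL_PA] * len(auto_pa_ids),
            }
        ),
    )
    return SimResult(snp=snp, pa=pa, registry=registry, truth=truth)


def write_simulation(sim: SimResult, outdir) -> dict[str, Path]:
    """Write snp.csv, pa.csv, sexes.csv and truth.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "snp": outdir / "snp.csv",
        "pa": outdir / "pa.csv",
        "sexes": outdir / "sexes.csv",
        "truth": outdir / "truth.tsv",
    }
    write_snp_table(sim.snp, paths["snp"])
    write_pa_table(sim.pa, paths["pa"])
    write_sex_registry(sim.registry, paths["sexes"])
    sim.truth.write_tsv(paths["truth"])
    return paths
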