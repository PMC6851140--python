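"""Genotypic sexing from discovered sex-linked markers.

Under an XY system a marker votes "male" when the SNP call is
heterozygous (or the presence/absence call is PRESENT) and "female" when
homozygous reference (or ABSENT); under ZW the votes are mirrored.
Null calls are uninformative.  A homozygous-alternate call at a
perfectly sex-linked locus is impossible under the clean model, so it
votes for *neither* sex and lowers concordance rather than being
silently dropped.  SNP and presence/absence votes are pooled with equal
weight.  The default unanimity of 1.0 requires every informative marker
to agree ("perfectly conformed"); lower it for noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calls import PaCall, SnpCall
from .matrices import PresenceMatrix, SexRegistry, SnpMatrix
from .scan import System

__all__ = ["SexCall", "assign_sex", "flag_discordance", "sex_ratio"]


@dataclass(frozen=True)
class SexCall:
    sample_id: str
    genotypic_sex: str  # 'M', 'F' or 'AMBIGUOUS'
    n_informative: int  # non-null sex-linked marker calls
    concordance: float  # fraction of informative markers agreeing with the call
    discordant_with_phenotype: bool = False


def _votes_for_sample(snp_calls, pa_calls, system: System) -> tuple[int, int, int]:
    """(male votes, female votes, informative count) for one sample."""
    het_vote, hom_vote = ("M", "F") if system is System.XY else ("F", "M")
    votes = {"M": 0, "F": 0}
    informative = 0
    for c in snp_calls:
        if c == SnpCall.NULL:
            continue
        informative += 1
        if c == SnpCall.HET:
            votes[het_vote] += 1
        elif c == SnpCall.HOM_REF:
            votes[hom_vote] += 1
        # HOM_ALT: informative but votes for neither sex
    for c in pa_calls:
        if c == PaCall.NULL:
            continue
        informative += 1
        if c == PaCall.PRESENT:
            votes[het_vote] += 1
        else:
            votes[hom_vote] += 1
    return votes["M"], votes["F"], informative


def assign_sex(
    snp: SnpMatrix | None,
    pa: PresenceMatrix | None,
    perfect_snp_loci=(),
    pa_linked_loci=(),
    system="XY",
    samples=None,
    unanimity: float = 1.0,
) -> list[SexCall]:
    """Genotypically sex samples from the discovered sex-linked loci.

    A sample is called M (or F) when at least ``unanimity`` of its
    informative markers vote that way; otherwise AMBIGUOUS.  Raises if a
    requested sample appears in neither matrix, or if no loci are given.
    """
    system = System(system)
    if system is System.UNDETERMINED:
        raise ValueError("cannot assign sex under an undetermined system")
    perfect_snp_loci = list(perfect_snp_loci)
    pa_linked_loci = list(pa_linked_loci)
    if not perfect_snp_loci and not pa_linked_loci:
        raise ValueError("no sex-linked loci supplied")
    if samples is None:
        pool: list[str] = []
        for m in (snp, pa):
            if m is not None:
                pool += [s for s in m.sample_ids if s not in pool]
        samples = pool

    snp_rows = (
        np.array([snp.locus_index(x) for x in perfect_snp_loci], dtype=int)
        if snp is not None and perfect_snp_loci
        else None
    )
    pa_rows = (
        np.array([pa.locus_index(x) for x in pa_linked_loci], dtype=int)
        if pa is not None and pa_linked_loci
        else None
    )

    calls = []
    for sample in samples:
        snp_calls: np.ndarray = np.empty(0, dtype=np.int8)
        pa_calls: np.ndarray = np.empty(0, dtype=np.int8)
        found = False
        if snp is not None and sample in set(snp.sample_ids):
            found = True
            if snp_rows is not None:
                snp_calls = snp.calls[snp_rows, snp.sample_index(sample)]
        if pa is not None and sample in set(pa.sample_ids):
            found = True
            if pa_rows is not None:
                pa_calls = pa.calls[pa_rows, pa.sample_index(sample)]
        if not found:
            raise KeyError(f"sample {sample!r} absent from both matrices")
        vm, vf, informative = _votes_for_sample(snp_calls, pa_calls, system)
        if informative == 0:
            calls.append(SexCall(sample, "AMBIGUOUS", 0, 0.0))
            continue
        concordance = max(vm, vf) / informative
        if vm / informative >= unanimity and vm > vf:
            sex = "M"
        elif vf / informative >= unanimity and vf > vm:
            sex = "F"
        else:
            sex = "AMBIGUOUS"
        calls.append(SexCall(sample, sex, informative, concordance))
    return calls


def flag_discordance(calls, registry: SexRegistry) -> list[SexCall]:
    """Mark calls whose confident phenotype contradicts the genotype.

    Unknown (U) phenotypes and AMBIGUOUS genotypes are never discordant.
    """
    out = []
    for call in calls:
        phenotype = registry.sex_of(call.sample_id)
        discordant = (
            phenotype in ("M", "F")
            and call.genotypic_sex in ("M", "F")
            and phenotype != call.genotypic_sex
        )
        out.append(replace(call, discordant_with_phenotype=discordant))
    return out


def sex_ratio(registry: SexRegistry, calls=()) -> float:
    """Male fraction: (phenotypic males + genotypic males among unknowns) / total."""
    genotypic = {c.sample_id: c.genotypic_sex for c in calls}
    n_male = len(registry.males)
    n_male += sum(1 for s in registry.unknowns if genotypic.get(s) == "M")
    return n_male / len(registry)


def sex_calls_frame(calls, registry: SexRegistry | None = None) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "phenotype": registry.sex_of(c.sample_id) if registry else "",
                "genotypic_sex": c.genotypic_sex,
                "n_informative": c.n_informative,
                "concordance": c.concordance,
                "discordant": c.discordant_with_phenotype,
            }
        )
    return pd.DataFrame(rows)
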