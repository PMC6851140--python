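"""Call categories for DArTseq-style genotype tables.

SNP calls use the DArT convention: ``0`` = homozygous for the reference
allele, ``1`` = homozygous for the alternate (SNP-carrying) allele,
``2`` = heterozygous, ``-`` = null allele (fragment not confidently
scored).  SilicoDArT presence/absence calls: ``1`` = restriction fragment
present, ``0`` = absent, ``-`` = null (non-zero counts, too low to call).
"""

from enum import IntEnum


class SnpCall(IntEnum):
    """One SNP genotype call.  Integer values equal the DArT file tokens."""

    NULL = -1
    HOM_REF = 0
    HOM_ALT = 1
    HET = 2


class PaCall(IntEnum):
    """One presence/absence call."""

    NULL = -1
    ABSENT = 0
    PRESENT = 1


# token <-> code maps used by the readers/writers
SNP_TOKEN_TO_CALL = {
    "0": SnpCall.HOM_REF,
    "1": SnpCall.HOM_ALT,
    "2": SnpCall.HET,
    "-": SnpCall.NULL,
}
SNP_CALL_TO_TOKEN = {v: k for k, v in SNP_TOKEN_TO_CALL.items()}

PA_TOKEN_TO_CALL = {
    "1": PaCall.PRESENT,
    "0": PaCall.ABSENT,
    "-": PaCall.NULL,
}
PA_CALL_TO_TOKEN = {v: k for k, v in PA_TOKEN_TO_CALL.items()}

SEX_CODES = ("M", "F", "U")
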