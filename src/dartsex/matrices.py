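"""In-memory containers for genotype matrices and the sex registry.

A :class:`SnpMatrix` (or :class:`PresenceMatrix`) is a loci x samples grid
of categorical calls plus the per-locus metadata DArT reports (marker id,
allele sequences, call rate, reproducibility).  Call rate and
reproducibility are treated as *upstream metadata*: filtering uses them
as given and nothing in the pipeline recomputes them.

A :class:`SexRegistry` maps each sample to its phenotypic sex (``M``,
``F`` or ``U`` for unknown) and an optional sampling-site label.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np

from .calls import SEX_CODES, PaCall, SnpCall

__all__ = ["SnpMatrix", "PresenceMatrix", "SexRegistry"]


def _as_str_array(values: Iterable, name: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def _check_unique(ids: np.ndarray, what: str) -> None:
    seen: set = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


def _check_fractions(values: np.ndarray, name: str) -> None:
    if np.any(values < 0) or np.any(values > 1) or np.any(~np.isfinite(values)):
        raise ValueError(f"{name} values must lie in [0, 1]")


class _CallMatrix:
    """Shared machinery of the SNP and presence/absence containers."""

    _valid_codes: frozenset

    def __init__(self, locus_ids, sample_ids, calls, call_rate=None, reproducibility=None):
        self.locus_ids = _as_str_array(locus_ids, "locus_ids")
        self.sample_ids = _as_str_array(sample_ids, "sample_ids")
        _check_unique(self.locus_ids, "locus")
        _check_unique(self.sample_ids, "sample")
        self.calls = np.asarray(calls, dtype=np.int8)
        if self.calls.shape != (len(self.locus_ids), len(self.sample_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"({len(self.locus_ids)} loci, {len(self.sample_ids)} samples)"
            )
        bad = ~np.isin(self.calls, list(self._valid_codes))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call code {int(self.calls[i, j])} at "
                f"locus {self.locus_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        n = len(self.locus_ids)
        self.call_rate = (
            np.ones(n) if call_rate is None else np.asarray(call_rate, dtype=float)
        )
        self.reproducibility = (
            np.ones(n) if reproducibility is None else np.asarray(reproducibility, dtype=float)
        )
        for name in ("call_rate", "reproducibility"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per locus")
            _check_fractions(arr, name)

    # -- basic introspection -------------------------------------------------
    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def locus_index(self, locus_id: str) -> int:
        idx = np.nonzero(self.locus_ids == locus_id)[0]
        if len(idx) == 0:
            raise KeyError(f"unknown locus {locus_id!r}")
        return int(idx[0])

    def sample_index(self, sample_id: str) -> int:
        idx = np.nonzero(self.sample_ids == sample_id)[0]
        if len(idx) == 0:
            raise KeyError(f"unknown sample {sample_id!r}")
        return int(idx[0])

    def calls_for_locus(self, locus_id: str) -> np.ndarray:
        return self.calls[self.locus_index(locus_id)]

    def _meta_arrays(self) -> dict[str, np.ndarray]:  # pragma: no cover - overridden
        raise NotImplementedError

    def subset_loci(self, which) -> "_CallMatrix":
        """Sub-matrix restricted to given loci (boolean mask, indices or ids).

        Locus order follows the mask/index order; samples are untouched.
        """
        which = np.asarray(which)
        if which.dtype == bool:
            idx = np.nonzero(which)[0]
        elif np.issubdtype(which.dtype, np.integer):
            idx = which
        else:
            idx = np.array([self.locus_index(x) for x in which], dtype=int)
        meta = {k: v[idx] for k, v in self._meta_arrays().items()}
        return type(self)(
            self.locus_ids[idx],
            self.sample_ids,
            self.calls[idx],
            call_rate=self.call_rate[idx],
            reproducibility=self.reproducibility[idx],
            **meta,
        )

    def __eq__(self, other) -> bool:
        if type(other) is not type(self):
            return NotImplemented
        return (
            np.array_equal(self.locus_ids, other.locus_ids)
            and np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.call_rate, other.call_rate)
            and np.array_equal(self.reproducibility, other.reproducibility)
            and all(
                np.array_equal(a, b)
                for a, b in zip(
                    self._meta_arrays().values(), other._meta_arrays().values()
                )
            )
        )

    __hash__ = None  # mutable container

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {self.n_loci} loci x {self.n_samples} samples>"


class SnpMatrix(_CallMatrix):
    """Loci x samples grid of SNP calls with per-locus DArT metadata.

    Parameters
    ----------
    locus_ids, sample_ids : sequences of unique strings.
    calls : integer array of :class:`~dartsex.calls.SnpCall` codes,
        shape ``(n_loci, n_samples)``.
    ref_seq, alt_seq : per-locus allele sequences; may be empty strings
        (simulated data carries no sequences - they are reported, never
        computed on).
    call_rate, reproducibility : per-locus fractions in [0, 1], default 1.
    """

    _valid_codes = frozenset(int(c) for c in SnpCall)

    def __init__(
        self,
        locus_ids,
        sample_ids,
        calls,
        *,
        ref_seq=None,
        alt_seq=None,
        call_rate=None,
        reproducibility=None,
    ):
        super().__init__(locus_ids, sample_ids, calls, call_rate, reproducibility)
        n = self.n_loci
        empty = np.array([""] * n, dtype=object)
        self.ref_seq = empty.copy() if ref_seq is None else _as_str_array(ref_seq, "ref_seq")
        self.alt_seq = empty.copy() if alt_seq is None else _as_str_array(alt_seq, "alt_seq")
        for name in ("ref_seq", "alt_seq"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one value per locus")

    def _meta_arrays(self):
        return {"ref_seq": self.ref_seq, "alt_seq": self.alt_seq}


class PresenceMatrix(_CallMatrix):
    """Loci x samples grid of SilicoDArT presence/absence calls."""

    _valid_codes = frozenset(int(c) for c in PaCall)

    def __init__(
        self,
        locus_ids,
        sample_ids,
        calls,
        *,
        sequence=None,
        call_rate=None,
        reproducibility=None,
    ):
        super().__init__(locus_ids, sample_ids, calls, call_rate, reproducibility)
        n = self.n_loci
        if sequence is None:
            self.sequence = np.array([""] * n, dtype=object)
        else:
            self.sequence = _as_str_array(sequence, "sequence")
        if len(self.sequence) != n:
            raise ValueError("sequence must have one value per locus")

    def _meta_arrays(self):
        return {"sequence": self.sequence}


class SexRegistry:
    """Per-sample phenotypic sex (``M``/``F``/``U``) and optional site label."""

    def __init__(self, sexes: Mapping[str, str], sites: Mapping[str, str] | None = None):
        self._sex: dict[str, str] = {}
        for sample, sex in sexes.items():
            code = str(sex).strip().upper()
            if code not in SEX_CODES:
                raise ValueError(f"invalid sex code {sex!r} for sample {sample!r}")
            if sample in self._sex:
                raise ValueError(f"duplicate sample id: {sample!r}")
            self._sex[str(sample)] = code
        self._site: dict[str, str] = dict(sites) if sites else {}

    # -- lookups -------------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self._sex)

    def __len__(self) -> int:
        return len(self._sex)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._sex

    def sex_of(self, sample_id: str) -> str:
        try:
            return self._sex[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in sex registry") from None

    def site_of(self, sample_id: str) -> str | None:
        return self._site.get(sample_id)

    @property
    def has_sites(self) -> bool:
        return any(v not in (None, "") for v in self._site.values())

    def sexes_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Sex codes aligned with ``sample_ids`` (KeyError on a missing sample)."""
        return np.array([self.sex_of(s) for s in sample_ids], dtype=object)

    def sites_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.array([self._site.get(s, "") or "" for s in sample_ids], dtype=object)

    def of_sex(self, code: str) -> list[str]:
        return [s for s, x in self._sex.items() if x == code]

    @property
    def males(self) -> list[str]:
        return self.of_sex("M")

    @property
    def females(self) -> list[str]:
        return self.of_sex("F")

    @property
    def unknowns(self) -> list[str]:
        return self.of_sex("U")

    @property
    def n_confident(self) -> int:
        """Number of confidently sexed samples (phenotype M or F)."""
        return len(self) - len(self.unknowns)

    # -- derived registries ---------------------------------------------------
    def augmented(self, genotypic: Mapping[str, str]) -> "SexRegistry":
        """Registry with unknown phenotypes replaced by genotypic assignments.

        ``genotypic`` maps sample id -> ``M``/``F``/``AMBIGUOUS``; only ``U``
        entries are replaced, and only by a confident M/F call.
        """
        sexes = dict(self._sex)
        for sample, sex in genotypic.items():
            if sexes.get(sample) == "U" and sex in ("M", "F"):
                sexes[sample] = sex
        return SexRegistry(sexes, self._site)

    def swapped(self) -> "SexRegistry":
        """Registry with every M relabelled F and vice versa (U unchanged)."""
        flip = {"M": "F", "F": "M", "U": "U"}
        return SexRegistry({s: flip[x] for s, x in self._sex.items()}, self._site)

    def items(self):
        return self._sex.items()

    def __eq__(self, other) -> bool:
        if not isinstance(other, SexRegistry):
            return NotImplemented
        return self._sex == other._sex and self._site == other._site

    __hash__ = None

    def __repr__(self) -> str:
        m, f, u = len(self.males), len(self.females), len(self.unknowns)
        return f"<SexRegistry {len(self)} samples: {m} M, {f} F, {u} U>"
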