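"""End-to-end sex-linkage analysis as a fitted-model object.

:class:`SexLinkageModel` bundles the inputs (SNP matrix, presence/absence
matrix, sex registry) with the analysis settings; :meth:`~SexLinkageModel.fit`
runs the full pipeline in the analysis order

    quality filter -> discovery scan (both hypotheses) -> system inference
    -> spurious-linkage budget -> genotypic sexing of unknowns
    -> moderate-locus scan on the augmented registry -> lineage grouping
    and Welch t-test -> Nei distances / PCoA / F_ST

and returns a :class:`SexLinkageResults` carrying every intermediate
table, a text :meth:`~SexLinkageResults.summary` and writers for the
per-stage TSV reports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import popgen, qc, scan as scan_mod, sexing
from .groups import (
    GroupAssignment,
    Group,
    MaleHetProfile,
    WelchResult,
    assign_groups,
    male_het_profiles,
    welch_t_from_values,
)
from .io import read_pa_table, read_sex_registry, read_snp_table
from .matrices import PresenceMatrix, SexRegistry, SnpMatrix
from .popgen import DistanceMatrix, PcoaResult
from .qc import FilterReport, FilterThresholds
from .scan import LinkageReport, SpuriousEstimate, System

__all__ = ["SexLinkageModel", "SexLinkageResults"]


class SexLinkageModel:
    """Sex-linked marker discovery model for one population sample.

    Parameters
    ----------
    snp, pa : the genotype matrices (either may be None, not both).
    registry : phenotypic sexes and optional site labels.
    thresholds : quality-filter settings.
    pa_min_prop : presence/absence linkage threshold (default 0.90).
    min_het_prop : male-heterozygosity floor for moderate loci.
    unanimity : fraction of informative markers that must agree for a
        genotypic sex call (1.0 = perfectly conformed).
    group_high, group_low : lineage-group thresholds on the per-male
        heterozygous fraction.
    pcoa_axes : number of principal-coordinate axes to retain.
    """

    def __init__(
        self,
        snp: SnpMatrix | None,
        pa: PresenceMatrix | None,
        registry: SexRegistry,
        *,
        thresholds: FilterThresholds | None = None,
        pa_min_prop: float = 0.9,
        require_contradiction_free: bool = True,
        min_het_prop: float = 0.25,
        unanimity: float = 1.0,
        group_high: float = 0.85,
        group_low: float = 0.20,
        pcoa_axes: int = 2,
    ):
        if snp is None and pa is None:
            raise ValueError("need at least one of the SNP / PA matrices")
        for m in (snp, pa):
            if m is not None:
                for s in m.sample_ids:
                    registry.sex_of(s)  # KeyError -> every sample must be registered
        self.snp = snp
        self.pa = pa
        self.registry = registry
        self.thresholds = thresholds or FilterThresholds()
        self.pa_min_prop = pa_min_prop
        self.require_contradiction_free = require_contradiction_free
        self.min_het_prop = min_het_prop
        self.unanimity = unanimity
        self.group_high = group_high
        self.group_low = group_low
        self.pcoa_axes = pcoa_axes

    @classmethod
    def from_files(cls, snp_path=None, pa_path=None, sexes_path=None, **kwargs):
        if sexes_path is None:
            raise ValueError("a sex registry file is required")
        return cls(
            read_snp_table(snp_path) if snp_path else None,
            read_pa_table(pa_path) if pa_path else None,
            read_sex_registry(sexes_path),
            **kwargs,
        )

    # ------------------------------------------------------------------
    def fit(self) -> "SexLinkageResults":
        """Run the full analysis; returns the results object."""
        filter_reports: list[FilterReport] = []
        snp_f = pa_f = None
        if self.snp is not None:
            snp_f, rep = qc.filter_snp(self.snp, self.thresholds)
            filter_reports.append(rep)
        if self.pa is not None:
            pa_f, rep = qc.filter_pa(self.pa, self.thresholds)
            filter_reports.append(rep)

        snp_scan = (
            scan_mod.scan_snp(snp_f, self.registry)
            if snp_f is not None and snp_f.n_loci
            else None
        )
        pa_scan = (
            scan_mod.scan_pa(
                pa_f,
                self.registry,
                min_prop=self.pa_min_prop,
                require_contradiction_free=self.require_contradiction_free,
            )
            if pa_f is not None and pa_f.n_loci
            else None
        )

        system = scan_mod.infer_system(
            len(snp_scan.perfect_xy) if snp_scan else 0,
            len(snp_scan.perfect_zw) if snp_scan else 0,
            len(pa_scan.linked_xy) if pa_scan else 0,
            len(pa_scan.linked_zw) if pa_scan else 0,
        )

        n_confident = self.registry.n_confident
        spurious = {}
        if snp_f is not None:
            spurious["snp"] = SpuriousEstimate(n=n_confident, m=snp_f.n_loci)
        if pa_f is not None:
            spurious["pa"] = SpuriousEstimate(n=n_confident, m=pa_f.n_loci)

        perfect_loci = snp_scan.perfect(system) if snp_scan and system is not System.UNDETERMINED else []
        pa_loci = pa_scan.linked(system) if pa_scan and system is not System.UNDETERMINED else []

        # genotypic sexing of every sample from the discovered markers
        sex_calls: list[sexing.SexCall] = []
        augmented = self.registry
        if system is not System.UNDETERMINED and (perfect_loci or pa_loci):
            sex_calls = sexing.assign_sex(
                snp_f,
                pa_f,
                perfect_loci,
                pa_loci,
                system,
                unanimity=self.unanimity,
            )
            sex_calls = sexing.flag_discordance(sex_calls, self.registry)
            augmented = self.registry.augmented(
                {c.sample_id: c.genotypic_sex for c in sex_calls}
            )

        moderate_loci: list[str] = []
        if snp_scan is not None and system is not System.UNDETERMINED:
            moderate_loci = scan_mod.find_moderate_loci(
                snp_f,
                augmented,
                system,
                min_het_prop=self.min_het_prop,
                perfect_loci=perfect_loci,
            )

        linkage = LinkageReport(
            inferred_system=system,
            perfect_snp_loci=list(perfect_loci),
            moderate_snp_loci=list(moderate_loci),
            pa_linked_loci=list(pa_loci),
            snp_scan=snp_scan,
            pa_scan=pa_scan,
            spurious=spurious,
        )

        # lineage grouping over the moderate loci
        profiles: list[MaleHetProfile] = []
        grouping: GroupAssignment | None = None
        welch: WelchResult | None = None
        if moderate_loci and system in (System.XY, System.ZW):
            het_sex = "M" if system is System.XY else "F"
            het_samples = [
                s
                for s in snp_f.sample_ids
                if augmented.sex_of(s) == het_sex
            ]
            profiles = male_het_profiles(snp_f, moderate_loci, het_samples)
            grouping = assign_groups(profiles, self.group_high, self.group_low)
            frac = {p.sample_id: p.het_fraction for p in profiles}
            g2 = [100 * frac[s] for s in grouping.members(Group.MALES2)]
            g3 = [100 * frac[s] for s in grouping.members(Group.MALES3)]
            if len(g2) >= 2 and len(g3) >= 2:
                try:
                    welch = welch_t_from_values(g2, g3)
                except ValueError:
                    welch = None

        # population structure
        fst_matrix = overall_fst = None
        if snp_f is not None and snp_f.n_loci and self.registry.has_sites:
            try:
                fst_matrix, overall_fst = popgen.pairwise_fst(snp_f, self.registry)
            except ValueError:
                pass
        nei = pcoa_result = None
        sexlinked = list(perfect_loci) + list(moderate_loci)
        if sexlinked and snp_f is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nei = popgen.nei_distance(snp_f, sexlinked)
                pcoa_result = popgen.pcoa(nei, k=self.pcoa_axes)

        ratio = sexing.sex_ratio(self.registry, sex_calls) if sex_calls else None

        return SexLinkageResults(
            model=self,
            filter_reports=filter_reports,
            snp_filtered=snp_f,
            pa_filtered=pa_f,
            linkage=linkage,
            sex_calls=sex_calls,
            augmented_registry=augmented,
            profiles=profiles,
            grouping=grouping,
            welch=welch,
            fst=fst_matrix,
            overall_fst=overall_fst,
            nei=nei,
            pcoa=pcoa_result,
            sex_ratio_male=ratio,
        )


@dataclass
class SexLinkageResults:
    """Everything :meth:`SexLinkageModel.fit` produced."""

    model: SexLinkageModel
    filter_reports: list[FilterReport]
    snp_filtered: SnpMatrix | None
    pa_filtered: PresenceMatrix | None
    linkage: LinkageReport
    sex_calls: list
    augmented_registry: SexRegistry
    profiles: list
    grouping: GroupAssignment | None
    welch: WelchResult | None
    fst: DistanceMatrix | None
    overall_fst: float | None
    nei: DistanceMatrix | None
    pcoa: PcoaResult | None
    sex_ratio_male: float | None

    # -- convenience ---------------------------------------------------------
    @property
    def inferred_system(self) -> System:
        return self.linkage.inferred_system

    @property
    def group_counts(self) -> dict[str, int]:
        if self.grouping is None:
            return {}
        return {g.value: c for g, c in self.grouping.counts.items()}

    def group_stats(self, group: Group) -> tuple[int, float, float]:
        """(n, mean, sd) of the percent heterozygosity inside one group."""
        if self.grouping is None:
            raise ValueError("no grouping available")
        frac = {p.sample_id: p.het_fraction for p in self.profiles}
        values = np.array([100 * frac[s] for s in self.grouping.members(group)])
        if len(values) == 0:
            return 0, float("nan"), float("nan")
        sd = float(values.std(ddof=1)) if len(values) > 1 else float("nan")
        return len(values), float(values.mean()), sd

    def summary_dict(self) -> dict:
        """Machine-readable summary (the numbers behind :meth:`summary`)."""
        reg = self.model.registry
        out = {
            "n_samples": len(reg),
            "n_phenotypic_males": len(reg.males),
            "n_phenotypic_females": len(reg.females),
            "n_unknown_sex": len(reg.unknowns),
            "inferred_system": self.inferred_system.value,
            "n_perfect_snp_loci": len(self.linkage.perfect_snp_loci),
            "n_pa_linked_loci": len(self.linkage.pa_linked_loci),
            "n_moderate_snp_loci": len(self.linkage.moderate_snp_loci),
            "filters": {
                r.stage: {"input": r.input_loci, "retained": r.retained_loci}
                for r in self.filter_reports
            },
            "spurious": {
                key: {
                    "n": est.n,
                    "m": est.m,
                    "p_per_locus": est.p_per_locus,
                    "expected_spurious": est.expected_spurious,
                }
                for key, est in self.linkage.spurious.items()
            },
        }
        if self.sex_ratio_male is not None:
            out["sex_ratio_male_percent"] = 100 * self.sex_ratio_male
            out["n_discordant"] = sum(
                1 for c in self.sex_calls if c.discordant_with_phenotype
            )
            unknowns = set(reg.unknowns)
            assigned = {
                c.sample_id: c.genotypic_sex
                for c in self.sex_calls
                if c.sample_id in unknowns
            }
            out["unknowns_assigned_male"] = sum(1 for v in assigned.values() if v == "M")
            out["unknowns_assigned_female"] = sum(1 for v in assigned.values() if v == "F")
        if self.grouping is not None:
            out["group_counts"] = self.group_counts
            for grp in (Group.MALES1, Group.MALES2, Group.MALES3):
                n, mean, sd = self.group_stats(grp)
                out[f"{grp.value.lower()}_het_percent"] = {"n": n, "mean": mean, "sd": sd}
        if self.welch is not None:
            out["welch"] = {
                "t": self.welch.t,
                "df": self.welch.df,
                "df_floor": self.welch.df_floor,
                "p_two_tailed": self.welch.p_two_tailed,
            }
        if self.overall_fst is not None:
            out["overall_fst"] = self.overall_fst
            out["max_pairwise_fst"] = float(np.max(self.fst.values))
        return out

    def summary(self) -> str:
        """Human-readable run summary."""
        d = self.summary_dict()
        lines = [
            "Sex-linkage analysis summary",
            "=" * 60,
            f"Samples: {d['n_samples']} "
            f"({d['n_phenotypic_males']} M, {d['n_phenotypic_females']} F, "
            f"{d['n_unknown_sex']} unknown)",
        ]
        for stage, counts in d["filters"].items():
            lines.append(
                f"Filter [{stage}]: {counts['retained']} of {counts['input']} loci retained"
            )
        lines += [
            f"Inferred system: {d['inferred_system']}",
            f"Perfectly sex-linked SNP loci: {d['n_perfect_snp_loci']}",
            f"Sex-linked PA loci: {d['n_pa_linked_loci']}",
            f"Moderately sex-linked SNP loci: {d['n_moderate_snp_loci']}",
        ]
        for key, est in d["spurious"].items():
            lines.append(
                f"Spurious-linkage budget [{key}]: "
                f"P per locus = 0.5^{est['n']} = {est['p_per_locus']:.3e}; "
                f"expected over {est['m']} loci = {est['expected_spurious']:.3e}"
            )
        if "sex_ratio_male_percent" in d:
            lines.append(
                f"Genotypic sexing: {d['unknowns_assigned_male']} unknown(s) male, "
                f"{d['unknowns_assigned_female']} female; "
                f"{d['n_discordant']} phenotype-genotype discordance(s)"
            )
            lines.append(f"Sex ratio: {d['sex_ratio_male_percent']:.1f}% male")
        if "group_counts" in d:
            counts = d["group_counts"]
            lines.append(
                "Male lineage groups: "
                + ", ".join(
                    f"{g}={counts.get(g, 0)}"
                    for g in ("MALES1", "MALES2", "MALES3", "UNASSIGNED")
                )
            )
            for g in ("males2", "males3"):
                stats = d.get(f"{g}_het_percent")
                if stats and stats["n"]:
                    lines.append(
                        f"  {g}: mean het {stats['mean']:.1f}% (s.d. {stats['sd']:.2f}%, n={stats['n']})"
                    )
        if "welch" in d:
            w = d["welch"]
            lines.append(
                f"Welch t-test (Males2 vs Males3): t({w['df_floor']}) = {w['t']:.2f}, "
                f"p = {w['p_two_tailed']:.3e} (two-tailed)"
            )
        if "overall_fst" in d:
            lines.append(
                f"F_ST: overall {d['overall_fst']:.4f}, "
                f"max pairwise {d['max_pairwise_fst']:.4f}"
            )
        return "\n".join(lines)

    # -- reports -------------------------------------------------------------
    def to_files(self, outdir, plots: bool = False) -> list[Path]:
        """Write every stage report into ``outdir``; returns written paths.

        Output is deterministic: running twice on the same inputs yields
        byte-identical files.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []

        def _write_df(df: pd.DataFrame, name: str):
            path = outdir / name
            df.to_csv(path, sep="\t", index=False)
            written.append(path)

        qc.write_filter_report(self.filter_reports, outdir / "filter_report.tsv")
        written.append(outdir / "filter_report.tsv")

        snp_table = self.linkage.snp_locus_table()
        if len(snp_table):
            _write_df(snp_table, "linkage_snp.tsv")
        pa_table = self.linkage.pa_locus_table()
        if len(pa_table):
            _write_df(pa_table, "linkage_pa.tsv")
        if self.sex_calls:
            _write_df(
                sexing.sex_calls_frame(self.sex_calls, self.model.registry),
                "sex_calls.tsv",
            )
        if self.grouping is not None:
            _write_df(self.grouping.to_frame(self.profiles), "groups.tsv")
        if self.nei is not None:
            self.nei.write_tsv(outdir / "nei_distances.tsv")
            written.append(outdir / "nei_distances.tsv")
        if self.pcoa is not None:
            _write_df(
                self.pcoa.to_frame().reset_index(names="sample_id"),
                "pcoa_coordinates.tsv",
            )
            eig = pd.DataFrame(
                {
                    "axis": [f"axis{i + 1}" for i in range(len(self.pcoa.eigenvalues))],
                    "eigenvalue": self.pcoa.eigenvalues,
                    "proportion_explained": self.pcoa.proportion_explained,
                }
            )
            _write_df(eig, "pcoa_eigenvalues.tsv")
        if self.fst is not None:
            self.fst.write_tsv(outdir / "fst_pairwise.tsv")
            written.append(outdir / "fst_pairwise.tsv")

        summary = self.summary_dict()
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(outdir / "summary.json")
        with open(outdir / "summary.md", "w", encoding="utf-8") as fh:
            fh.write("# Sex-linkage analysis\n\n```\n" + self.summary() + "\n```\n")
        written.append(outdir / "summary.md")

        if plots:
            written += self._write_plots(outdir)
        return written

    # -- plotting ------------------------------------------------------------
    def plot_heatmap(self, ax=None):
        """Nei-distance heat map over the sex-linked loci (requires nei)."""
        import matplotlib.pyplot as plt
        import seaborn as sns

        if self.nei is None:
            raise ValueError("no Nei distance matrix available")
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 7))
        sns.heatmap(self.nei.to_frame(), cmap="coolwarm", square=True, ax=ax)
        ax.set_title("Nei genetic distance (sex-linked loci)")
        return ax

    def plot_pcoa(self, ax=None):
        import matplotlib.pyplot as plt

        if self.pcoa is None:
            raise ValueError("no PCoA result available")
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        coords = self.pcoa.coordinates
        sexes = self.augmented_registry.sexes_for(self.pcoa.sample_ids)
        for code, colour in (("M", "tab:blue"), ("F", "tab:red"), ("U", "tab:gray")):
            mask = sexes == code
            if mask.any():
                ax.scatter(coords[mask, 0], coords[mask, 1], label=code, c=colour, s=25)
        prop = self.pcoa.proportion_explained
        ax.set_xlabel(f"Axis 1 ({100 * prop[0]:.1f}%)")
        if coords.shape[1] > 1:
            ax.set_ylabel(f"Axis 2 ({100 * prop[1]:.1f}%)")
        ax.legend(title="sex")
        return ax

    def _write_plots(self, outdir: Path) -> list[Path]:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        written = []
        if self.nei is not None:
            ax = self.plot_heatmap()
            path = outdir / "nei_heatmap.png"
            ax.figure.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
            written.append(path)
        if self.pcoa is not None:
            ax = self.plot_pcoa()
            path = outdir / "pcoa.png"
            ax.figure.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
            written.append(path)
        return written
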