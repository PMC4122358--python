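"""End-to-end pipeline: orthology -> masking -> deltas -> statistics -> tables.

For every unordered pair of species (in the user-declared phylogenetic
order) the pipeline infers RBH orthologs, extends them to internal-intron
sequences, computes signed (delta_bpi, delta_gci) records before and after
repeat masking, filters negligible pairs, and emits percent-positive
summaries, four-class frequencies with exact binomial tests (BH-adjusted
across the whole family of comparison x masking-variant tests), per-species
composition tables and, when respirometry traces are supplied, SNK
comparisons of metabolic rate and Spearman correlations between the
per-comparison mean deltas.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .deltas import (
    ClassCounts,
    adjust_fdr,
    binomial_test_top_class,
    class_frequencies,
    compute_deltas,
    filter_deltas,
    percent_positive,
    summarize_comparison,
)
from .errors import ParameterError
from .metabolism import RespirometryTrace, metabolic_rate_record
from .orthology import LocalProteinScorer, all_vs_all_hits, extend_to_introns, reciprocal_best_hits
from .repeats import RepeatLibrary, apply_mask_to_dataset, mask_stats
from .seqmodel import SpeciesDataset, apply_qc, dataset_summary
from .stats import distribution_stats, snk_test, spearman


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    species: dict[str, dict]  # species_id -> {"fasta":..., "gff":..., "traces":[...]}
    order: list[str]
    masking: str = "both"  # both | before | after
    gc_threshold: float = 0.1
    bp_threshold: float = 100.0
    binomial_null: float = 0.25
    outdir: str | None = None
    seed: int = 0
    kmer_prefilter: int | None = 4
    min_shared_kmers: int = 2
    score_min: float = 50.0

    def __post_init__(self) -> None:
        if len(self.species) < 2:
            raise ParameterError("at least two species required")
        if sorted(self.order) != sorted(self.species):
            raise ParameterError("order must be a permutation of the species list")


@dataclass
class ReportBundle:
    species_summary: pd.DataFrame
    mask_summary: pd.DataFrame
    gci_distributions: pd.DataFrame
    comparisons: pd.DataFrame
    class_table: pd.DataFrame
    removed_table: pd.DataFrame
    spearman_table: pd.DataFrame | None = None
    snk_table: pd.DataFrame | None = None
    mr_table: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        for name in (
            "species_summary",
            "mask_summary",
            "gci_distributions",
            "comparisons",
            "class_table",
            "removed_table",
            "spearman_table",
            "snk_table",
            "mr_table",
        ):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(
    datasets: Mapping[str, SpeciesDataset],
    order: Sequence[str],
    repeat_library: RepeatLibrary | None = None,
    traces: Mapping[str, Sequence[RespirometryTrace]] | None = None,
    masking: str = "both",
    gc_threshold: float = 0.1,
    bp_threshold: float = 100.0,
    binomial_null: float = 0.25,
    kmer_prefilter: int | None = 4,
    min_shared_kmers: int = 2,
    score_min: float = 50.0,
    outdir: str | None = None,
    seed: int = 0,
    known_pairs: Mapping[tuple[str, str], Sequence] | None = None,
) -> ReportBundle:
    """Run the full comparative analysis over every unordered species pair.

    ``order`` fixes the orientation of each comparison (earlier species is
    ``m``); masking runs both variants by default when a repeat library is
    supplied.  ``known_pairs`` lets callers inject externally determined
    ortholog pairs per (m, z) comparison, bypassing the built-in RBH step.
    """
    if sorted(order) != sorted(datasets):
        raise ParameterError("order must be a permutation of the dataset keys")
    if masking not in {"both", "before", "after"}:
        raise ParameterError("masking must be 'both', 'before' or 'after'")
    variants = {"both": ("before", "after"), "before": ("before",), "after": ("after",)}[masking]
    if "after" in variants and repeat_library is None:
        variants = ("before",)

    qc_data: dict[str, SpeciesDataset] = {}
    qc_reports: dict[str, dict[str, int]] = {}
    for sp in order:
        qc_data[sp], qc_reports[sp] = apply_qc(datasets[sp])

    masked_data: dict[str, SpeciesDataset] = {}
    mask_rows = []
    if "after" in variants and repeat_library is not None:
        for sp in order:
            masked_data[sp], results = apply_mask_to_dataset(qc_data[sp], lib=repeat_library)
            ms = mask_stats(results)
            mask_rows.append(
                {
                    "species": sp,
                    "mean_bp_pct": ms.mean_bp_pct,
                    "se_bp_pct": ms.se_bp_pct,
                    "mean_gc_pct": ms.mean_gc_pct,
                    "se_gc_pct": ms.se_gc_pct,
                    "n": ms.n,
                }
            )

    scorer = LocalProteinScorer()
    comp_rows = []
    class_rows = []
    removed_rows = []
    pvalues = []
    comparison_means: dict[str, dict[str, float]] = {}

    for sp_m, sp_z in itertools.combinations(order, 2):
        cid = f"{sp_m}-{sp_z}"
        if known_pairs is not None and (sp_m, sp_z) in known_pairs:
            pairs = list(known_pairs[(sp_m, sp_z)])
        else:
            hits_ab = all_vs_all_hits(
                qc_data[sp_m].protein_seqs,
                qc_data[sp_z].protein_seqs,
                scorer=scorer,
                score_min=score_min,
                kmer_prefilter=kmer_prefilter,
                min_shared_kmers=min_shared_kmers,
            )
            hits_ba = all_vs_all_hits(
                qc_data[sp_z].protein_seqs,
                qc_data[sp_m].protein_seqs,
                scorer=scorer,
                score_min=score_min,
                kmer_prefilter=kmer_prefilter,
                min_shared_kmers=min_shared_kmers,
            )
            pairs = reciprocal_best_hits(hits_ab, hits_ba, species_m=sp_m, species_z=sp_z)

        for variant in variants:
            dm = masked_data[sp_m] if variant == "after" else qc_data[sp_m]
            dz = masked_data[sp_z] if variant == "after" else qc_data[sp_z]
            intron_pairs, dropped = extend_to_introns(pairs, dm, dz)
            records = compute_deltas(intron_pairs, masked_variant=variant)
            retained, removed_fraction = filter_deltas(
                records, gc_threshold=gc_threshold, bp_threshold=bp_threshold
            )
            if not retained:
                continue
            summary = summarize_comparison(retained, comparison_id=cid)
            counts = class_frequencies(
                retained, comparison_id=cid, n_filtered_out=len(records) - len(retained)
            )
            p_raw = binomial_test_top_class(counts, null_p=binomial_null)
            pvalues.append(p_raw)
            comp_rows.append(
                {
                    "comparison": cid,
                    "variant": variant,
                    "n_rbh_pairs": len(pairs),
                    "n_intron_pairs": len(records),
                    "n_dropped_intronless": dropped,
                    "n_retained": summary.n,
                    "pct_positive_gci": summary.pct_positive_gci,
                    "pct_positive_bpi": summary.pct_positive_bpi,
                    "mean_delta_gci": summary.mean_delta_gci,
                    "mean_delta_bpi": summary.mean_delta_bpi,
                    "top_class": counts.top_class,
                    "binomial_p": p_raw,
                }
            )
            pct = counts.percentages
            class_rows.append(
                {
                    "comparison": cid,
                    "variant": variant,
                    **{f"n_{lbl.replace('/', '')}": counts.counts[lbl] for lbl in counts.counts},
                    **{f"pct_{lbl.replace('/', '')}": pct[lbl] for lbl in pct},
                }
            )
            removed_rows.append(
                {
                    "comparison": cid,
                    "variant": variant,
                    "n_records": len(records),
                    "n_removed": len(records) - len(retained),
                    "removed_pct": removed_fraction,
                }
            )
            if variant == "before":
                comparison_means[cid] = {
                    "mean_delta_bpi": summary.mean_delta_bpi,
                    "mean_delta_gci": summary.mean_delta_gci,
                }

    comparisons = pd.DataFrame(comp_rows)
    if pvalues:
        comparisons["binomial_p_adj"] = adjust_fdr(list(comparisons["binomial_p"]))

    species_rows = []
    dist_rows = []
    for sp in order:
        s = dataset_summary(qc_data[sp])
        s["species"] = sp
        s.update({f"qc_{k}": v for k, v in qc_reports[sp].items()})
        species_rows.append(s)
        gcis = [i.gci for i in qc_data[sp].intronic_seqs.values() if i.gci is not None]
        if len(gcis) >= 3 and np.std(gcis) > 0:
            d = distribution_stats(gcis)
            dist_rows.append(
                {"species": sp, "n": d.n, "mean_gci": d.mean, "sd": d.sd, "skewness": d.skewness}
            )

    mr_table = None
    snk_df = None
    spearman_df = None
    mean_mr: dict[str, float] = {}
    if traces:
        mr_rows = []
        mr_groups: dict[str, list[float]] = {}
        for sp, sp_traces in traces.items():
            for tr in sp_traces:
                rec = metabolic_rate_record(tr)
                mr_rows.append(
                    {"species": sp, "mr0": rec.mr0, "t_kelvin": rec.t_kelvin, "mr": rec.mr}
                )
                mr_groups.setdefault(sp, []).append(rec.mr)
        mr_table = pd.DataFrame(mr_rows)
        mean_mr = {sp: float(np.mean(v)) for sp, v in mr_groups.items()}
        if len(mr_groups) >= 2 and all(len(v) >= 2 for v in mr_groups.values()):
            snk = snk_test({sp: np.log(mr_groups[sp]) for sp in order if sp in mr_groups})
            snk_df = pd.DataFrame(
                [
                    {"species_a": a, "species_b": b, "decision": d}
                    for (a, b), d in sorted(snk.decisions.items())
                ]
            )

    if comparison_means and mean_mr and len(comparison_means) >= 4:
        cids = sorted(comparison_means)
        d_bpi = [comparison_means[c]["mean_delta_bpi"] for c in cids]
        d_gci = [comparison_means[c]["mean_delta_gci"] for c in cids]
        d_mr = [mean_mr[c.split("-")[0]] - mean_mr[c.split("-")[1]] for c in cids]
        rows = []
        for (na, va), (nb, vb) in itertools.combinations(
            [("delta_bpi", d_bpi), ("delta_gci", d_gci), ("delta_mr", d_mr)], 2
        ):
            res = spearman(va, vb)
            rows.append({"x": na, "y": nb, "rho": res.rho, "p_value": res.p_value, "n": res.n})
        spearman_df = pd.DataFrame(rows)

    manifest = {
        "package_version": _pkg_version,
        "seed": seed,
        "species_order": list(order),
        "masking_variants": list(variants),
        "gc_threshold": gc_threshold,
        "bp_threshold": bp_threshold,
        "binomial_null": binomial_null,
        "n_comparisons": len({r["comparison"] for r in comp_rows}),
        "config_hash": _config_hash(
            {
                "order": list(order),
                "masking": masking,
                "gc_threshold": gc_threshold,
                "bp_threshold": bp_threshold,
                "binomial_null": binomial_null,
                "seed": seed,
                "score_min": score_min,
                "kmer_prefilter": kmer_prefilter,
            }
        ),
    }

    bundle = ReportBundle(
        species_summary=pd.DataFrame(species_rows),
        mask_summary=pd.DataFrame(mask_rows),
        gci_distributions=pd.DataFrame(dist_rows),
        comparisons=comparisons,
        class_table=pd.DataFrame(class_rows),
        removed_table=pd.DataFrame(removed_rows),
        spearman_table=spearman_df,
        snk_table=snk_df,
        mr_table=mr_table,
        manifest=manifest,
    )
    if outdir:
        bundle.write(outdir)
    return bundle
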