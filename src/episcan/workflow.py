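"""End-to-end analysis pipeline over a synthetic dataset.

Wires the stages in the order a real study would run them: simulate (or
load) inputs, test overlap enrichment per feature, build the
feature-centered profile, compute condition set algebra and gene-context
statistics, score radial position, and train the matched-null classifier.
Every stochastic stage receives a seed derived from one master seed, so a
run is fully reproducible from its manifest.
"""

from __future__ import annotations

import json
import os
from typing import Optional

import numpy as np
import pandas as pd

from . import context, features_ml, profiles, radial
from .core import IntervalSet
from .enrichment import permutation_enrichment
from .simulate import SimConfig, SyntheticDataset, generate_dataset, write_dataset


def union_sets(sets: list[IntervalSet], label: str = "union") -> IntervalSet:
    frames = [s.to_dataframe() for s in sets if len(s)]
    genome = next((s.genome for s in sets if s.genome is not None), None)
    if not frames:
        return IntervalSet(genome=genome, label=label)
    df = pd.concat(frames, ignore_index=True)
    return IntervalSet.from_dataframe(df, genome=genome, label=label)


def derived_seeds(master_seed: int, n: int) -> list[int]:
    """Independent integer sub-seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31 - 1)) for s in state]


def run_all(
    config: Optional[SimConfig] = None,
    seed: int = 0,
    outdir: Optional[str] = None,
    n_iterations: int = 1000,
    n_trees: int = 700,
) -> dict:
    """Simulate and analyze; returns a nested result dict (JSON-safe)."""
    cfg = config or SimConfig()
    cfg = SimConfig(**{**cfg.to_dict(), "seed": seed,
                       "genes_per_class": tuple(cfg.genes_per_class)})
    s_enrich, s_null, s_clf = derived_seeds(seed, 3)

    dataset = generate_dataset(cfg)
    results: dict = {"seed": seed, "config": cfg.to_dict()}

    # ---- overlap enrichment of each condition in each feature set
    enrich = {}
    for cond, dsbs in dataset.dsbs.items():
        enrich[cond] = {}
        for fname in ("H3K36me3", "CTCF"):
            res = permutation_enrichment(
                dsbs, dataset.features[fname], dataset.genome,
                n_iterations=n_iterations, seed=s_enrich,
            )
            d = res.to_dict()
            d.pop("null_counts")
            enrich[cond][fname] = d
    results["enrichment"] = enrich

    # ---- condition set algebra and gene context
    nt, dmso, aph = (dataset.dsbs[c] for c in ("NT", "DMSO", "APH"))
    shared_nt, unique_nt = context.condition_sets(nt, [dmso, aph])
    shared_dmso, unique_dmso = context.condition_sets(dmso, [nt])
    results["condition_sets"] = {
        "nt_shared_fraction": len(shared_nt) / len(nt),
        "dmso_unique_count": len(unique_dmso),
    }
    results["genic_fraction"] = {
        "DMSO_unique": context.genic_fraction(unique_dmso, dataset.gene_set)
        if len(unique_dmso) else None,
        "APH": context.genic_fraction(aph, dataset.gene_set),
    }
    results["chromosome_density"] = {
        cond: context.chromosome_density(ds, dataset.genome)
        for cond, ds in dataset.dsbs.items()
    }
    results["gene_size_stats"] = {
        cond: context.gene_size_stats(ds, dataset.genes).to_dataframe().to_dict("records")
        for cond, ds in dataset.dsbs.items()
    }

    # ---- feature-centered profiles
    prof = {}
    for cond, fname in (("APH", "CTCF"), ("DMSO", "H3K36me3"), ("DMSO", "TSS")):
        p = profiles.aggregate_profile(dataset.dsbs[cond], dataset.features[fname])
        prof[f"{cond}_vs_{fname}"] = {
            "mode": p.mode,
            "counts": p.bin_counts.tolist(),
            "top_bins": np.argsort(p.bin_counts)[::-1][:2].tolist(),
        }
    results["profiles"] = prof

    # ---- radial position
    rad = {}
    for cond in ("NT", "DMSO", "APH"):
        summary = radial.radial_scores(dataset.dsbs[cond], dataset.gpseq)
        _, p_shift = summary.shift_test()
        rad[cond] = {
            "mean_dsb_score": float(summary.dsb_scores.mean()),
            "mean_background_score": float(summary.background_scores.mean()),
            "n_unscored": summary.n_unscored,
            "shift_p": p_shift,
        }
    results["radial"] = rad

    # ---- matched-null classification on the treatment-unique DSBs
    # (classification is sharpest on the induced subset, so the real class
    # is the condition-unique set, nulls matched per region)
    real = unique_dmso
    exclude = union_sets([nt, dmso, aph], label="all_dsbs")
    nulls = features_ml.sample_matched_nulls(real, dataset.genome, exclude, seed=s_null)
    matrix = features_ml.build_feature_matrix(
        real, nulls, tracks=dataset.tracks, mode="signal"
    )
    report = features_ml.train_evaluate(matrix, n_trees=n_trees, seed=s_clf)
    results["classifier"] = report.to_dict()

    dist_matrix = features_ml.build_feature_matrix(
        real, nulls, feature_sets=dataset.features, mode="distance"
    )
    dist_report = features_ml.train_evaluate(dist_matrix, n_trees=n_trees, seed=s_clf)
    results["classifier_distance"] = dist_report.to_dict()

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_dataset(dataset, os.path.join(outdir, "data"))
        matrix.to_tsv(os.path.join(outdir, "feature_matrix_signal.tsv"))
        with open(os.path.join(outdir, "results.json"), "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return results
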