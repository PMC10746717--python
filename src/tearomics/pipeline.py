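"""End-to-end orchestration: one config, one seed, a directory of tables.

Stages write files rather than passing objects so each stage can be
re-run and inspected independently:

  cohort -> preprocess -> 4 classifiers (multiclass + one-vs-rest per
  level) -> training metrics -> attributions -> rankings (unweighted,
  incl_bl, excl_bl) -> rank comparisons -> differential abundance.

A manifest (JSON) lists every output file with its SHA-256 digest plus
the run parameters, so two runs with the same config and seed can be
checked for byte identity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tearomics import abundance, attribution, models, preprocess, simulate, weighting
from tearomics.containers import ClinicalTable, ProteinQuantTable


@dataclass
class RunConfig:
    """Inputs and knobs for one full analysis run.

    Exactly one of ``sim`` (synthetic mode) or ``quant_path`` +
    ``clinical_path`` (file mode) must be given.
    """

    outdir: str | Path = "tearomics_run"
    sim: simulate.SimConfig | None = None
    quant_path: str | Path | None = None
    proteins_path: str | Path | None = None
    clinical_path: str | Path | None = None
    tau: float = weighting.DEFAULT_TAU
    top_k: int = 15
    q_max: float = 0.01
    fc_min: float = 2.0
    seed: int = 0
    ranking_signed: bool = False
    write_attributions: bool = False
    contaminant_rules: preprocess.ContaminantRules = field(
        default_factory=preprocess.ContaminantRules
    )

    def validate(self) -> None:
        file_mode = self.quant_path is not None
        if file_mode == (self.sim is not None):
            raise ValueError("give exactly one of sim config or input paths")
        if file_mode and (self.clinical_path is None or self.proteins_path is None):
            raise ValueError("file mode needs quant, proteins and clinical paths")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def emit(path: Path) -> Path:
        files.append(path)
        return path

    # --- stage: cohort --------------------------------------------------
    try:
        if config.sim is not None:
            quant, clinical = simulate.generate_cohort(config.sim)
        else:
            quant = ProteinQuantTable.from_tsv(config.quant_path, config.proteins_path)
            clinical = ClinicalTable.from_tsv(config.clinical_path)
        quant.to_tsv(emit(outdir / "quant.tsv"), emit(outdir / "proteins.tsv"))
        clinical.to_tsv(emit(outdir / "clinical.tsv"))
    except Exception as exc:
        raise RuntimeError(f"stage 'cohort' failed: {exc}") from exc

    # --- stage: preprocess ----------------------------------------------
    try:
        clinical, matrix, report = preprocess.preprocess_pipeline(
            clinical, quant, rules=config.contaminant_rules
        )
        matrix.values.to_csv(emit(outdir / "features.tsv"), sep="\t", index_label="sample_id")
        matrix.transform_params.to_csv(
            emit(outdir / "transform_params.tsv"), sep="\t", index_label="accession"
        )
        _write_json(emit(outdir / "preprocess_report.json"), report.to_json_dict())
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc

    levels = clinical.levels
    unique_levels = sorted(set(int(v) for v in levels))
    names = quant.names

    # per-task deterministic seeds from the one run seed
    task_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                  np.random.SeedSequence(config.seed).spawn(1 + len(unique_levels))]

    tasks = [models.TaskSpec(kind="multiclass", seed=task_seeds[0])]
    tasks += [
        models.TaskSpec(kind="one_vs_rest", target_level=lv, seed=task_seeds[i + 1])
        for i, lv in enumerate(unique_levels)
    ]

    raw_encoded = preprocess.encode_special_values(
        preprocess.drop_undetected(
            preprocess.filter_contaminants(
                quant.subset_samples(clinical.sample_ids), config.contaminant_rules
            )
        )
    )

    for task in tasks:
        tag = "multiclass" if task.kind == "multiclass" else f"level{task.target_level}"
        try:
            model = models.train_classifier(matrix, levels, task)
            metrics = models.evaluate_training_fit(model, matrix, levels)
            model.booster.save_model(str(emit(outdir / f"model_{tag}.txt")))
            _write_json(emit(outdir / f"metrics_{tag}.json"), metrics.to_json_dict())
        except Exception as exc:
            raise RuntimeError(f"stage 'train:{tag}' failed: {exc}") from exc

        try:
            attr = attribution.compute_attributions(model, matrix)
            if config.write_attributions:
                attr.to_long_tsv(emit(outdir / f"attributions_{tag}.tsv"))
            proba = model.predict_probabilities(matrix)
            pred = model.class_labels[np.argmax(proba, axis=1)]
            p_pred = proba[np.arange(proba.shape[0]), np.argmax(proba, axis=1)]
            y_true = levels if task.kind == "multiclass" else models.binarize_labels(
                levels, task.target_level
            )
            records = weighting.group_predictions(
                pred, p_pred, true_labels=y_true, tau=config.tau,
                sample_ids=matrix.sample_ids,
            )
            class_of_interest = None if task.kind == "multiclass" else 1

            base = weighting.aggregate_importance(
                attr, class_of_interest, k=config.top_k, signed=config.ranking_signed
            )
            w_incl = weighting.weight_attributions(attr, records, proba, mode="incl_bl")
            r_incl = weighting.aggregate_importance(
                w_incl, class_of_interest, k=config.top_k, signed=config.ranking_signed
            )
            w_excl = weighting.weight_attributions(attr, records, proba, mode="excl_bl")
            r_excl = weighting.aggregate_importance(
                w_excl, class_of_interest, k=config.top_k, signed=config.ranking_signed
            )

            cmp_incl = weighting.compare_rankings(base, r_incl, k=config.top_k)
            cmp_excl = weighting.compare_rankings(base, r_excl, k=config.top_k)
            weighting.ranking_to_tsv(base, emit(outdir / f"ranking_{tag}_unweighted.tsv"), names)
            weighting.ranking_to_tsv(
                r_incl, emit(outdir / f"ranking_{tag}_incl_bl.tsv"), names, cmp_incl
            )
            weighting.ranking_to_tsv(
                r_excl, emit(outdir / f"ranking_{tag}_excl_bl.tsv"), names, cmp_excl
            )
            _write_json(
                emit(outdir / f"comparison_{tag}.json"),
                {
                    "incl_bl_new_entries": cmp_incl.new_in_b,
                    "excl_bl_new_entries": cmp_excl.new_in_b,
                    "group_counts": {
                        g: sum(1 for r in records if r.group == g)
                        for g in (weighting.POSITIVE, weighting.NEGATIVE, weighting.BORDERLINE)
                    },
                },
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'explain:{tag}' failed: {exc}") from exc

    # --- stage: differential abundance ----------------------------------
    try:
        diff = abundance.differential_analysis(
            raw_encoded.values, levels, q_max=config.q_max, fc_min=config.fc_min
        )
        diff.to_csv(emit(outdir / "differential_abundance.tsv"), sep="\t", index=False)
        pairs = [(a, b) for i, a in enumerate(unique_levels) for b in unique_levels[i + 1:]]
        rows = []
        for acc in diff.loc[diff["significant"], "accession"]:
            vals = raw_encoded.values[acc].to_numpy(dtype=float)
            for a, b in pairs:
                p = abundance.pairwise_level_test(vals, levels, a, b)
                rows.append((acc, a, b, p, abundance.significance_marker(p)))
        pd.DataFrame(rows, columns=["accession", "level_a", "level_b", "p", "marker"]).to_csv(
            emit(outdir / "pairwise_tests.tsv"), sep="\t", index=False
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'differential_abundance' failed: {exc}") from exc

    manifest = {
        "parameters": {
            "tau": config.tau,
            "top_k": config.top_k,
            "q_max": config.q_max,
            "fc_min": config.fc_min,
            "seed": config.seed,
            "ranking_aggregation": "signed_sum" if config.ranking_signed else "abs_sum",
            "probability_clip_eps": weighting.PROB_EPS,
            "log_transform": "log1p",
            "sim": None if config.sim is None else simulate.config_to_json_dict(config.sim),
        },
        "files": {p.name: _sha256(p) for p in sorted(files)},
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest
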