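"""Pipeline stages tying the library together, with rerun manifests.

Stage order: synth → curate → pathways → cohort → pretrain → finetune /
baseline → evaluate → interpret. Each stage reads its upstream artefacts from
the run directory, writes its outputs plus a ``<stage>.manifest.json``
(config hash, seeds, input-file hashes, package version) and fails with a
:class:`PipelineError` naming the stage to run first when an upstream
artefact is missing.
"""

from __future__ import annotations

import csv
import hashlib
import json
from collections import defaultdict
from dataclasses import asdict
from datetime import date
from pathlib import Path

import numpy as np

import pathdx
from pathdx import io as pio
from pathdx.cohort import build_case_control, sample_ids, split_population
from pathdx.config import RunConfig
from pathdx.curation import curate_events, load_code_map
from pathdx.evaluation import (
    delong_compare,
    metrics_report,
    subgroup_report,
    threshold_sweep,
)
from pathdx.interpretation import (
    cluster_code_summary,
    cluster_pathways,
    embed_2d,
    extract_attention_profile,
    extract_cls_embedding,
)
from pathdx.model import SequenceModelConfig, load_checkpoint, save_checkpoint
from pathdx.pathways import (
    NoIndexDate,
    Pathway,
    Vocabulary,
    derive_pathway,
    filter_min_codes,
    select_index_date,
    strip_label_codes,
)
from pathdx.synthetic import SynthConfig, generate_cohort
from pathdx.training import (
    TrainPlan,
    encode_pathways,
    featurize_matrix,
    finetune,
    predict_scores,
    pretrain,
    train_lr_baseline,
)
from pathdx.vocab_spec import LUNG_DX, OTHER_CANCER_DX, RESPIRATORY_DX

STAGES = (
    "synth",
    "curate",
    "pathways",
    "cohort",
    "pretrain",
    "finetune",
    "baseline",
    "evaluate",
    "interpret",
)


class PipelineError(RuntimeError):
    pass


def _require(outdir: Path, filename: str, produced_by: str) -> Path:
    p = outdir / filename
    if not p.exists():
        raise PipelineError(
            f"missing artefact {filename!r}: run stage {produced_by!r} first"
        )
    return p


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, config: RunConfig, inputs: list[Path],
                    outputs: list[Path], seeds: dict[str, int]) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "inputs": {p.name: _hash_file(p) for p in inputs if p.exists()},
        "outputs": [p.name for p in outputs],
        "pathdx_version": pathdx.__version__,
    }
    (outdir / f"{stage}.manifest.json").write_text(json.dumps(manifest, indent=2))


def _model_config(config: RunConfig, vocab_size: int) -> SequenceModelConfig:
    if config.preset == "desk":
        return SequenceModelConfig.desk(
            vocab_size=vocab_size, max_len=config.pathway.max_len
        )
    return SequenceModelConfig(vocab_size=vocab_size, max_len=config.pathway.max_len)


def _plan(section) -> TrainPlan:
    return TrainPlan(
        batch_size=section.batch_size,
        epochs=section.epochs,
        learning_rate=section.learning_rate,
        restarts=section.restarts,
        seed=section.seed,
    )


# --- stage implementations ---------------------------------------------------


def stage_synth(config: RunConfig, outdir: Path) -> None:
    from dataclasses import replace

    from pathdx.synthetic import desk_config

    s = config.synth
    base = desk_config() if config.preset == "desk" else SynthConfig()
    synth_cfg = replace(
        base,
        n_patients=s.n_patients,
        case_fraction=s.case_fraction,
        vocab_size=s.vocab_size,
        mean_pathway_length=s.mean_pathway_length,
        signal_mode=s.signal_mode,
        seed=s.seed,
    )
    cohort = generate_cohort(synth_cfg)
    cohort.write(outdir)
    _write_manifest(
        outdir, "synth", config, [],
        [outdir / f for f in ("patients.csv", "events.csv", "codemap.csv", "ground_truth.csv")],
        {"synth": s.seed},
    )


def stage_curate(config: RunConfig, outdir: Path) -> None:
    events_path = (
        Path(config.events_path) if config.events_path
        else _require(outdir, "events.csv", "synth")
    )
    codemap_path = (
        Path(config.codemap_path) if config.codemap_path
        else _require(outdir, "codemap.csv", "synth")
    )
    code_map = load_code_map(codemap_path)
    curated = curate_events(pio.read_events(events_path), code_map)
    out = outdir / "curated_events.csv"
    with out.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "event_date", "group_id"])
        for e in curated:
            w.writerow([e.patient_id, e.event_date.isoformat(), e.group_id])
    _write_manifest(outdir, "curate", config, [events_path, codemap_path], [out], {})


def _read_curated(outdir: Path) -> dict[str, list]:
    from pathdx.curation import CuratedEvent

    path = _require(outdir, "curated_events.csv", "curate")
    by_pid: dict[str, list] = defaultdict(list)
    with path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            by_pid[row["patient_id"]].append(
                CuratedEvent(
                    row["patient_id"],
                    date.fromisoformat(row["event_date"]),
                    row["group_id"],
                )
            )
    return by_pid


def stage_pathways(config: RunConfig, outdir: Path) -> None:
    by_pid = _read_curated(outdir)
    codemap_path = (
        Path(config.codemap_path) if config.codemap_path
        else _require(outdir, "codemap.csv", "synth")
    )
    code_map = load_code_map(codemap_path)
    dx_codes = set(code_map.groups_in_category("diagnosis"))
    lung, cancer, resp = {LUNG_DX}, set(OTHER_CANCER_DX), set(RESPIRATORY_DX)
    pw = config.pathway
    pathways: list[Pathway] = []
    n_no_index = 0
    for pid in sorted(by_pid):
        events = by_pid[pid]
        try:
            index_date, stratum = select_index_date(
                events, lung, cancer, diagnostic_codes=dx_codes, respiratory_codes=resp
            )
        except NoIndexDate:
            n_no_index += 1
            continue
        p = derive_pathway(
            events, index_date, int(stratum == "lung"), stratum, pid,
            lookback_months=pw.lookback_months, trim_months=pw.trim_months,
        )
        pathways.append(p)
    kept = filter_min_codes(pathways, pw.min_codes)
    out = outdir / "pathways.jsonl"
    with out.open("w", encoding="utf-8") as fh:
        for p in kept:
            fh.write(json.dumps({
                "patient_id": p.patient_id,
                "index_date": p.index_date.isoformat(),
                "label": p.label,
                "stratum": p.stratum,
                "tokens": p.tokens,
            }) + "\n")
    summary = {
        "n_pathways": len(kept),
        "n_excluded_min_codes": len(pathways) - len(kept),
        "n_no_index": n_no_index,
        "vocabulary_size": code_map.vocabulary_size,
    }
    (outdir / "pathways_summary.json").write_text(json.dumps(summary, indent=2))
    _write_manifest(outdir, "pathways", config,
                    [outdir / "curated_events.csv"], [out], {})


def read_pathways(outdir: Path) -> list[Pathway]:
    path = _require(outdir, "pathways.jsonl", "pathways")
    out = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            d = json.loads(line)
            out.append(Pathway(
                patient_id=d["patient_id"],
                tokens=d["tokens"],
                index_date=date.fromisoformat(d["index_date"]),
                label=d["label"],
                stratum=d["stratum"],
            ))
    return out


def stage_cohort(config: RunConfig, outdir: Path) -> None:
    pathways = read_pathways(outdir)
    cs = config.cohort
    split = split_population(
        [p.patient_id for p in pathways], cs.train_fraction, seed=cs.seed
    )
    by_pid = {p.patient_id: p for p in pathways}
    train_paths = [by_pid[i] for i in split.training]
    cc = build_case_control(train_paths, cs.stratum_quotas, seed=cs.seed)
    cc_ids = [p.patient_id for p in cc.pathways]
    eval_ids = sample_ids(cc_ids, min(cs.eval_size, len(cc_ids) // 3), seed=cs.seed + 1)
    val_ids = split.validation
    if cs.validation_sample_size and cs.validation_sample_size < len(val_ids):
        val_sample = sample_ids(val_ids, cs.validation_sample_size, seed=cs.seed + 2)
    else:
        val_sample = val_ids
    out = outdir / "cohort.json"
    out.write_text(json.dumps({
        "training": split.training,
        "validation": split.validation,
        "case_control": cc_ids,
        "evaluation": eval_ids,
        "validation_sample": val_sample,
        "composition": cc.composition,
    }, indent=2))
    _write_manifest(outdir, "cohort", config, [outdir / "pathways.jsonl"], [out],
                    {"cohort": cs.seed})


def _load_cohort(outdir: Path) -> dict:
    return json.loads(_require(outdir, "cohort.json", "cohort").read_text())


def _vocabulary(outdir: Path, config: RunConfig) -> Vocabulary:
    codemap_path = (
        Path(config.codemap_path) if config.codemap_path
        else _require(outdir, "codemap.csv", "synth")
    )
    return Vocabulary.from_groups(load_code_map(codemap_path).vocabulary)


def stage_pretrain(config: RunConfig, outdir: Path) -> None:
    pathways = {p.patient_id: p for p in read_pathways(outdir)}
    cohort = _load_cohort(outdir)
    vocab = _vocabulary(outdir, config)
    train_paths = [pathways[i] for i in cohort["case_control"]]
    # pretraining keeps each pathway ending in its diagnostic endpoint code
    by_pid = _read_curated(outdir)
    endpoints = {}
    for p in train_paths:
        same_day = [e.group_id for e in by_pid[p.patient_id]
                    if e.event_date == p.index_date]
        if same_day:
            endpoints[p.patient_id] = same_day[-1]
    mcfg = _model_config(config, len(vocab))
    seqs = encode_pathways(train_paths, vocab, mcfg.max_len, endpoints=endpoints)
    result = pretrain(seqs, mcfg, _plan(config.pretrain_plan))
    save_checkpoint(result.model, outdir / "pretrained")
    trace_path = outdir / "pretrain_loss.csv"
    with trace_path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["step", "loss", "smoothed"])
        for i, (l, s) in enumerate(zip(result.loss_trace, result.smoothed_trace)):
            w.writerow([i, l, s])
    _write_manifest(outdir, "pretrain", config, [outdir / "pathways.jsonl"],
                    [outdir / "pretrained.npz", trace_path],
                    {"pretrain": config.pretrain_plan.seed})


def _finetune_sets(config: RunConfig, outdir: Path):
    pathways = {p.patient_id: p for p in read_pathways(outdir)}
    cohort = _load_cohort(outdir)
    vocab = _vocabulary(outdir, config)
    lung, cancer = {LUNG_DX}, set(OTHER_CANCER_DX)

    def stripped(ids):
        return [strip_label_codes(pathways[i], lung, cancer) for i in ids]

    eval_ids = set(cohort["evaluation"])
    train_ids = [i for i in cohort["case_control"] if i not in eval_ids]
    return (
        stripped(train_ids),
        stripped(sorted(eval_ids)),
        stripped(cohort["validation_sample"]),
        vocab,
    )


def stage_finetune(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "pretrained.npz", "pretrain")
    train_paths, eval_paths, _, vocab = _finetune_sets(config, outdir)
    pre = load_checkpoint(outdir / "pretrained")
    max_len = pre.config.max_len
    seqs = encode_pathways(train_paths, vocab, max_len)
    eval_seqs = encode_pathways(eval_paths, vocab, max_len)
    result = finetune(
        seqs, [p.label for p in train_paths], pre, _plan(config.finetune_plan),
        eval_seqs, [p.label for p in eval_paths],
    )
    save_checkpoint(result.model, outdir / "finetuned")
    (outdir / "finetune_report.json").write_text(json.dumps({
        "best_restart": result.best_restart,
        "restarts": result.report,
    }, indent=2))
    _write_manifest(outdir, "finetune", config, [outdir / "pretrained.npz"],
                    [outdir / "finetuned.npz", outdir / "finetune_report.json"],
                    {"finetune": config.finetune_plan.seed})


def stage_baseline(config: RunConfig, outdir: Path) -> None:
    train_paths, _, val_paths, vocab = _finetune_sets(config, outdir)
    X = featurize_matrix(train_paths, vocab)
    clf = train_lr_baseline(X, [p.label for p in train_paths],
                            seed=config.finetune_plan.seed)
    scores = clf.predict_proba(featurize_matrix(val_paths, vocab))[:, 1]
    out = outdir / "baseline_scores.csv"
    with out.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "score", "label"])
        for p, s in zip(val_paths, scores):
            w.writerow([p.patient_id, f"{s:.6f}", p.label])
    _write_manifest(outdir, "baseline", config, [outdir / "pathways.jsonl"], [out],
                    {"baseline": config.finetune_plan.seed})


def _read_scores(path: Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    pids, scores, labels = [], [], []
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            pids.append(row["patient_id"])
            scores.append(float(row["score"]))
            labels.append(int(row["label"]))
    return pids, np.array(scores), np.array(labels)


def stage_evaluate(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "finetuned.npz", "finetune")
    baseline_path = _require(outdir, "baseline_scores.csv", "baseline")
    train_paths, eval_paths, val_paths, vocab = _finetune_sets(config, outdir)
    model = load_checkpoint(outdir / "finetuned")
    seqs = encode_pathways(val_paths, vocab, model.config.max_len)
    scores = predict_scores(model, seqs)
    labels = np.array([p.label for p in val_paths])
    out_scores = outdir / "model_scores.csv"
    with out_scores.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "score", "label"])
        for p, s in zip(val_paths, scores):
            w.writerow([p.patient_id, f"{s:.6f}", p.label])

    ev = config.evaluation
    report = metrics_report(scores, labels, threshold=ev.threshold,
                            n_boot=ev.n_boot, seed=ev.seed)
    sweep = threshold_sweep(scores, labels, ev.thresholds)
    pids_b, scores_b, labels_b = _read_scores(baseline_path)
    pid_order = {p.patient_id: i for i, p in enumerate(val_paths)}
    b_aligned = np.empty(len(val_paths))
    for pid, s in zip(pids_b, scores_b):
        if pid in pid_order:
            b_aligned[pid_order[pid]] = s
    diff, pval = delong_compare(scores, b_aligned, labels)
    baseline_rep = metrics_report(b_aligned, labels, threshold=ev.threshold)

    # demographics for subgroup panels
    sub = {}
    patients_path = (
        Path(config.patients_path) if config.patients_path
        else outdir / "patients.csv"
    )
    if patients_path.exists():
        demo = {p.patient_id: p for p in pio.read_patients(patients_path)}
        sub = subgroup_report(
            scores, labels,
            {
                "sex": [demo[p.patient_id].sex for p in val_paths],
                "ethnicity": [demo[p.patient_id].ethnicity for p in val_paths],
            },
            threshold=ev.threshold,
        )
        for attr in sub.values():
            for entry in attr.values():
                if "report" in entry:
                    entry["report"] = entry["report"].as_dict()

    out = outdir / "evaluation.json"
    out.write_text(json.dumps({
        "model": report.as_dict(),
        "baseline": baseline_rep.as_dict(),
        "delong": {"auroc_difference": diff, "p_value": pval},
        "threshold_sweep": [asdict(r) for r in sweep],
        "subgroups": sub,
    }, indent=2))

    md = [
        "# Evaluation report",
        "",
        f"- n = {report.n} validation patients ({report.n_positive} lung cancer)",
        f"- sequence model AUROC {report.auroc:.3f}; baseline AUROC {baseline_rep.auroc:.3f}",
        f"- DeLong difference {diff:+.3f} (p = {pval:.2g})",
        "",
        "| threshold | predicted + | true + | positives | sensitivity | PPV |",
        "|---|---|---|---|---|---|",
    ]
    for r in sweep:
        md.append(
            f"| {r.threshold:.2f} | {r.n_predicted_positive} | {r.n_true_positive} "
            f"| {r.n_positives} | {r.sensitivity:.1%} | {r.ppv:.1%} |"
        )
    (outdir / "evaluation.md").write_text("\n".join(md) + "\n")
    _write_manifest(outdir, "evaluate", config,
                    [outdir / "finetuned.npz", baseline_path],
                    [out_scores, out, outdir / "evaluation.md"],
                    {"evaluate": ev.seed})


def stage_interpret(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "finetuned.npz", "finetune")
    _, _, val_paths, vocab = _finetune_sets(config, outdir)
    model = load_checkpoint(outdir / "finetuned")
    it = config.interpretation
    seqs = encode_pathways(val_paths, vocab, model.config.max_len)
    emb = extract_cls_embedding(model, seqs)
    report = cluster_pathways(emb, k=it.k, seed=it.seed, n_init=it.n_init)
    profiles = [
        extract_attention_profile(model, p, vocab) for p in val_paths
    ]
    report = cluster_code_summary(report, val_paths, profiles)
    coords = embed_2d(emb, seed=it.seed, perplexity=it.perplexity)
    out = outdir / "clusters.json"
    out.write_text(json.dumps({
        "k": report.k,
        "sizes": report.sizes,
        "fractions": report.fractions,
        "inertia": report.inertia,
        "k_scan": report.k_scan,
        "code_prevalence": {str(c): v for c, v in report.code_prevalence.items()},
        "top_attended": {str(c): v for c, v in report.top_attended.items()},
    }, indent=2))
    with (outdir / "cluster_assignments.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "cluster", "x", "y"])
        for p, a, (x, y) in zip(val_paths, report.assignments, coords):
            w.writerow([p.patient_id, int(a), f"{x:.4f}", f"{y:.4f}"])
    _write_manifest(outdir, "interpret", config, [outdir / "finetuned.npz"],
                    [out, outdir / "cluster_assignments.csv"],
                    {"interpret": it.seed})


_STAGE_FNS = {
    "synth": stage_synth,
    "curate": stage_curate,
    "pathways": stage_pathways,
    "cohort": stage_cohort,
    "pretrain": stage_pretrain,
    "finetune": stage_finetune,
    "baseline": stage_baseline,
    "evaluate": stage_evaluate,
    "interpret": stage_interpret,
}


def run_stage(stage: str, config: RunConfig) -> Path:
    """Run one pipeline stage; returns the run directory."""
    if stage not in _STAGE_FNS:
        raise PipelineError(f"unknown stage {stage!r}; stages are {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _STAGE_FNS[stage](config, outdir)
    return outdir


def run_all(config: RunConfig) -> Path:
    for stage in STAGES:
        run_stage(stage, config)
    return Path(config.outdir)
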