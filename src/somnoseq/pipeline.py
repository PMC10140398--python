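"""End-to-end wiring: simulate -> preprocess -> cross-validate -> report.

These helpers connect the generators, the preprocessing chain and the
training driver; the command-line interface and the examples are thin
wrappers around them.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .metrics import agreement_table, consensus_analysis, is_undefined
from .nn.model import ModelConfig, TINY_PRESET
from .psg_io import downsample_recording, epochize, write_edf, write_hypnogram
from .simulate import default_scorer_model, derive_seed, generate_cohort, simulate_scorer
from .stages import Hypnogram, PsgRecording
from .training import CrossValidationResult, TrainingConfig, run_cross_validation

logger = logging.getLogger(__name__)

WORKING_RATE_HZ = 100.0


def prepare_recording(recording: PsgRecording,
                      target_rate: float = WORKING_RATE_HZ) -> np.ndarray:
    """Downsample to the working rate and cut into the 30-s epoch grid."""
    if recording.sampling_rate_hz != target_rate:
        recording = downsample_recording(recording, target_rate)
    return epochize(recording).astype(np.float32)


def prepare_cohort(
    pairs: list[tuple[PsgRecording, Hypnogram]],
    target_rate: float = WORKING_RATE_HZ,
) -> list[tuple[np.ndarray, Hypnogram, dict]]:
    """Preprocess a labelled cohort into cross-validation input triples."""
    out = []
    for rec, hyp in pairs:
        epochs = prepare_recording(rec, target_rate)
        n = min(len(epochs), len(hyp))  # guard: equal by construction
        meta = dict(rec.metadata)
        meta["id"] = rec.id
        out.append((epochs[:n], Hypnogram(hyp.codes[:n], hyp.source_id), meta))
    return out


def write_manifest(out_dir: Path, seed: int, config: dict,
                   inputs: dict[str, Path] | None = None) -> Path:
    """Reproducibility manifest: config, seed, version, input checksums."""
    manifest = {
        "somnoseq_version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {},
    }
    for name, path in (inputs or {}).items():
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        manifest["inputs"][name] = {"path": str(path), "sha256": digest}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def simulate_to_dir(
    out_dir: str | Path,
    n_recordings: int,
    epochs_per_recording: int,
    seed: int,
    rate: float = 200.0,
) -> Path:
    """Generate a cohort and write EDFs + hypnogram text + a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(n_recordings, epochs_per_recording, seed, rate=rate)
    rows = []
    for rec, hyp in cohort:
        write_edf(rec, out_dir / f"{rec.id}.edf")
        write_hypnogram(hyp, out_dir / f"{rec.id}.hypnogram.txt")
        rows.append({
            "id": rec.id, "group": rec.metadata["group"],
            "ahi": rec.metadata["ahi"], "n_epochs": len(hyp),
            "seed": rec.metadata["seed"],
        })
    with open(out_dir / "cohort.csv", "w", newline="") as f:
        w = csv.DictWriter(f, fieldnames=list(rows[0]))
        w.writeheader()
        w.writerows(rows)
    write_manifest(out_dir, seed, {
        "n_recordings": n_recordings,
        "epochs_per_recording": epochs_per_recording,
        "rate": rate,
    })
    logger.info("wrote %d recordings to %s", n_recordings, out_dir)
    return out_dir


def _clean(x):
    if isinstance(x, float) and is_undefined(x):
        return None
    return x


def write_cv_reports(result: CrossValidationResult, out_dir: str | Path) -> None:
    """Write pooled/per-fold/per-recording/groupwise reports + histories."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {
        "pooled": result.pooled_report.to_dict(),
        "per_fold": [r.to_dict() for r in result.per_fold_reports],
        "groups": {g: r.to_dict() for g, r in result.group_reports.items()},
    }
    (out_dir / "metrics.json").write_text(json.dumps(report, indent=2))
    result.plan.to_json(out_dir / "fold_plan.json")
    with open(out_dir / "per_recording.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["id", "accuracy", "kappa", "n_epochs"])
        for rid, d in result.per_recording.items():
            w.writerow([rid, f"{d['accuracy']:.4f}", f"{d['kappa']:.4f}",
                        d["n_epochs"]])
    for i, hist in enumerate(result.histories):
        hist.to_csv(out_dir / f"history_fold{i}.csv")
    cm = result.pooled_confusion
    with open(out_dir / "confusion.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["reference\\predicted"] + list(cm.labels))
        for lab, row in zip(cm.labels, cm.counts):
            w.writerow([lab] + list(map(int, row)))


def demo_pipeline(
    out_dir: str | Path,
    seed: int = 0,
    n_recordings: int = 4,
    epochs_per_recording: int = 60,
    k: int = 2,
    max_epochs: int = 3,
    model_config: ModelConfig | None = None,
) -> dict:
    """Desk-scale end-to-end loop: tiny cohort -> k-fold CV with the tiny
    model preset -> evaluation and rater-agreement reports.

    Returns the machine-readable summary that is also written to
    ``out_dir/demo_summary.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model_cfg = model_config or TINY_PRESET
    train_cfg = TrainingConfig(seq_len=model_cfg.seq_len, max_epochs=max_epochs,
                               batch_size=8, seed=seed)
    cohort = generate_cohort(n_recordings, epochs_per_recording,
                             seed=seed, rate=200.0)
    triples = prepare_cohort(cohort)
    result = run_cross_validation(triples, model_cfg, train_cfg, k=k)
    write_cv_reports(result, out_dir)

    # rater-agreement analysis on the first recording's reference scoring
    truth = triples[0][1]
    err = default_scorer_model()
    scorings = {
        name: simulate_scorer(truth, err, derive_seed(seed, 100 + j), source_id=name)
        for j, name in enumerate(["S1a", "S1b", "S2a", "S2b"])
    }
    auto = result.predictions[triples[0][2]["id"]]
    scorings["Auto"] = auto
    table = agreement_table(scorings, auto_ids={"Auto"})
    cons = consensus_analysis(scorings["S1a"], scorings["S2a"], auto)
    agreement = {
        pair: {
            "percent_agreement": round(pa.percent_agreement, 1),
            "kappa": round(pa.kappa, 4),
            "remark": pa.remark,
            "per_stage": {s: _clean(v) for s, v in pa.per_stage.items()},
        } for pair, pa in table.items()
    }
    summary = {
        "pooled_accuracy": result.pooled_report.accuracy,
        "pooled_kappa": result.pooled_report.kappa,
        "kappa_remark": result.pooled_report.kappa_remark,
        "n_epochs": result.pooled_report.n_epochs,
        "agreement": agreement,
        "consensus": {
            "consensus_fraction": cons.consensus_fraction,
            "consensus_accuracy": _clean(cons.consensus_accuracy),
            "consensus_kappa": _clean(cons.consensus_kappa),
            "match_at_least_one": cons.match_at_least_one,
        },
    }
    (out_dir / "demo_summary.json").write_text(json.dumps(summary, indent=2))
    write_manifest(out_dir, seed, {
        "model": asdict(model_cfg), "training": asdict(train_cfg),
        "n_recordings": n_recordings,
        "epochs_per_recording": epochs_per_recording, "k": k,
    })
    return summary
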