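"""End-to-end pipeline stages shared by the CLI and the test-bench.

Each stage is a plain function taking a resolved config dict and an output
directory, so the CLI stays a thin argument-parsing layer.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import map_labels, run_task
from .config import dump_config
from .errors import InsufficientCyclesError, PcgEmotionError, SegmentationError
from .features import build_matrix, combine_blocks, feature_block
from .indicators import ecg_rr, hs_dsv, hs_hrv
from .preprocess import lowpass, preselect, read_wav, shannon_envelope
from .segment import segment_pcg
from .synth import DEFAULT_PROFILES, make_dataset

log = logging.getLogger("pcg_emotion")


def _write_provenance(out_dir: Path, cfg: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, out_dir / "config.resolved.yaml")
    (out_dir / "provenance.json").write_text(json.dumps({
        "package": "pcg-emotion", "version": __version__, "seed": cfg["seed"],
    }, indent=2))


def run_synth(cfg: dict, out_dir: str | Path) -> pd.DataFrame:
    """Generate the synthetic labeled corpus described by the config."""
    out_dir = Path(out_dir)
    _write_provenance(out_dir, cfg)
    counts_cfg = cfg["synth"]["counts"]
    profiles = [DEFAULT_PROFILES[e] for e in counts_cfg]
    counts = [int(counts_cfg[e]) for e in counts_cfg]
    manifest = make_dataset(
        profiles, counts, out_dir / "corpus",
        segment_seconds=float(cfg["synth"]["segment_seconds"]),
        seed=int(cfg["seed"]),
        rate=float(cfg["synth"]["rate"]),
        snr_db=float(cfg["synth"]["snr_db"]),
    )
    log.info("synth: wrote %d segments to %s", len(manifest), out_dir / "corpus")
    return manifest


def run_extract(cfg: dict, corpus_dir: str | Path,
                out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Per-segment preselect -> segment -> indicators -> feature blocks.

    Segments failing the quality gate or segmentation are dropped with the
    reason logged to ``drops.csv``.  Writes one CSV per feature block plus
    the surviving label vector.
    """
    corpus_dir = Path(corpus_dir)
    out_dir = Path(out_dir)
    _write_provenance(out_dir, cfg)
    manifest = pd.read_csv(corpus_dir / "manifest.csv")
    if manifest.empty:
        raise PcgEmotionError("empty corpus manifest")

    pp = cfg["preprocess"]
    blocks: dict[str, list] = {"hs_hrv": [], "hs_dsv": [], "ecg_hrv": []}
    labels: list[str] = []
    ids: list[str] = []
    drops: list[dict] = []
    m_max = int(cfg["features"]["m_max"])

    for row in manifest.itertuples():
        try:
            rec = read_wav(corpus_dir / row.path)
            filtered = lowpass(rec, cutoff=float(pp["cutoff_hz"]),
                               order=int(pp["order"]))
            env = shannon_envelope(filtered, window=float(pp["envelope_window_s"]))
            gate = preselect(rec, env, config=cfg["preselect"])
            if not gate.passed:
                drops.append({"path": row.path, "stage": "preselect",
                              "reason": "; ".join(gate.reasons)})
                continue
            seg = segment_pcg(filtered, env, config=cfg["segment"])
            rr = hs_hrv(seg, source_id=row.path)
            ds = hs_dsv(seg, source_id=row.path)
            fv_rr = feature_block(rr, m_max=m_max)
            fv_ds = feature_block(ds, m_max=m_max)
        except (InsufficientCyclesError, SegmentationError, PcgEmotionError) as exc:
            drops.append({"path": row.path, "stage": "segment", "reason": str(exc)})
            continue
        blocks["hs_hrv"].append(fv_rr)
        blocks["hs_dsv"].append(fv_ds)
        truth_path = corpus_dir / (Path(row.path).stem + ".truth.json")
        if truth_path.exists():
            sidecar = json.loads(truth_path.read_text())
            if "rpeaks" in sidecar:
                series = ecg_rr(np.asarray(sidecar["rpeaks"]), source_id=row.path)
                blocks["ecg_hrv"].append(feature_block(series, m_max=m_max))
        labels.append(row.emotion)
        ids.append(row.path)

    pd.DataFrame(drops, columns=["path", "stage", "reason"]).to_csv(
        out_dir / "drops.csv", index=False)
    if not labels:
        raise PcgEmotionError("no segments survived the quality gates; "
                              f"{len(drops)} dropped")
    log.info("extract: %d segments kept, %d dropped", len(labels), len(drops))

    matrices: dict[str, pd.DataFrame] = {}
    for name in ("hs_hrv", "hs_dsv"):
        fm = build_matrix(blocks[name], ids=ids)
        matrices[name] = fm.data
    if len(blocks["ecg_hrv"]) == len(labels):
        matrices["ecg_hrv"] = build_matrix(blocks["ecg_hrv"], ids=ids).data
    hd_vectors = [combine_blocks(a, b)
                  for a, b in zip(blocks["hs_hrv"], blocks["hs_dsv"])]
    matrices["hs_hd"] = build_matrix(hd_vectors, ids=ids).data

    for name, df in matrices.items():
        df.to_csv(out_dir / f"features_{name}.csv", index_label="id")
    pd.DataFrame({"id": ids, "emotion": labels}).to_csv(
        out_dir / "labels.csv", index=False)
    return matrices


def run_classify(cfg: dict, features_dir: str | Path,
                 out_dir: str | Path) -> pd.DataFrame:
    """Selection + tuning + evaluation per (block, task); Table-shaped report.

    Rows are indicator blocks, columns the three tasks, entries CV accuracy
    in percent.
    """
    features_dir = Path(features_dir)
    out_dir = Path(out_dir)
    _write_provenance(out_dir, cfg)
    labels = pd.read_csv(features_dir / "labels.csv")
    ccfg = cfg["classify"]
    grid = {k: tuple(v) for k, v in ccfg["grid"].items()}

    table: dict[str, dict[str, float]] = {}
    for block in ("hs_hrv", "hs_dsv", "ecg_hrv", "hs_hd"):
        path = features_dir / f"features_{block}.csv"
        if not path.exists():
            log.warning("classify: block %s missing, skipped", block)
            continue
        df = pd.read_csv(path, index_col="id")
        table[block] = {}
        for task in ccfg["tasks"]:
            classes, counts = map_labels(labels["emotion"], task)
            result = run_task(
                df.to_numpy(), classes, block=block, task=task,
                n_runs=int(ccfg["n_runs"]), base_seed=int(cfg["seed"]),
                ga_config=ccfg["ga"], grid_config=grid,
                weight_threshold=float(ccfg["weight_threshold"]),
                folds=int(ccfg["folds"]))
            table[block][task] = result.cv_accuracy * 100.0
            artifact = {
                "block": block, "task": task, "class_counts": counts,
                "c": result.c, "g": result.g,
                "cv_accuracy": round(result.cv_accuracy, 4),
                "optimal_subset": np.flatnonzero(
                    result.aggregate.optimal_subset).tolist(),
                "weights": result.aggregate.weight.tolist(),
                "seeds": [r.seed for r in result.aggregate.runs],
                "report": result.report,
            }
            (out_dir / f"model_{block}_{task}.json").write_text(
                json.dumps(artifact, indent=2))
            traces = pd.concat(
                [r.fitness_trace.assign(run=r.seed)
                 for r in result.aggregate.runs], ignore_index=True)
            traces.to_csv(out_dir / f"trace_{block}_{task}.csv", index=False)
            log.info("classify: %s/%s accuracy %.4f", block, task,
                     result.cv_accuracy)

    report = pd.DataFrame(table).T
    report.index.name = "indicator"
    report.to_csv(out_dir / "comparison.csv", float_format="%.4f")
    return report
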