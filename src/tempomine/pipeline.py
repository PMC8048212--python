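"""End-to-end pipeline chaining ingest → dedup → merge → embed → cluster →
align → reconstruct → mine, with a reproducibility manifest.

Every stage writes a plain inspectable file (CSV / JSON-lines / JSON) into
the output directory and the manifest records each artifact's path and
SHA-256 content hash plus an echo of all parameters and seeds, so identical
configuration and inputs yield identical hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import corpus as corpus_io
from .errors import StageError
from .fingerprint import cluster_fingerprints, fingerprint_corpus
from .patterns import prefixspan, top_k_report
from .reconstruct import build_sequences, reconstruct_corpus
from .synth import GeneratorConfig, generate
from .timeline import align_external


@dataclass
class RunConfig:
    """All stage parameters for one pipeline run."""

    outdir: str = "tempomine_run"
    # input: either a corpus file or a synthetic generator configuration
    input_path: str | None = None
    input_format: str = "csv"
    anchors_path: str | None = None
    synthetic: GeneratorConfig | None = None
    # stage parameters
    dedup: bool = True
    merge_gap_hours: float | None = 24.0
    bits: int = 64
    weighting: str = "tf"
    hash_seed: int = 1
    k_clusters: int = 10
    cluster_seed: int = 1
    anchor: str = "discharge"
    k_entities: int = 10
    medoid_seed: int = 1
    mode: str = "timed"
    min_support: int = 2
    max_length: int | None = None
    top: int = 10


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "params": _params_dict(config)}

    def record(stage: str, path: Path):
        manifest["stages"][stage] = {"path": str(path), "sha256": _sha256(path)}

    def run_stage(stage: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - attributed and re-raised
            raise StageError(stage, exc, manifest) from exc

    # 1. ingest
    def _ingest():
        if config.synthetic is not None:
            corpus, truth = generate(config.synthetic)
            truth_path = outdir / "ground_truth.json"
            truth_path.write_text(_truth_json(truth), encoding="utf-8")
        elif config.input_path is not None:
            corpus = corpus_io.read_corpus(config.input_path, format=config.input_format)
            if config.anchors_path:
                corpus.anchor_times = corpus_io.load_anchor_times(config.anchors_path)
        else:
            raise ValueError("RunConfig needs either input_path or synthetic")
        path = outdir / "corpus.csv"
        corpus_io.write_corpus(corpus, path)
        corpus_io.save_anchor_times(corpus.anchor_times, outdir / "anchors.json")
        record("ingest", path)
        return corpus

    corpus = run_stage("ingest", _ingest)

    # 2. dedup
    def _dedup():
        deduped = corpus_io.deduplicate(corpus) if config.dedup else corpus
        path = outdir / "corpus_dedup.csv"
        corpus_io.write_corpus(deduped, path)
        record("dedup", path)
        return deduped

    deduped = run_stage("dedup", _dedup)

    # 3. merge
    def _merge():
        if config.merge_gap_hours is not None:
            merged = corpus_io.merge_adjacent(deduped, gap_hours=config.merge_gap_hours)
        else:
            merged = deduped
        path = outdir / "corpus_merged.csv"
        corpus_io.write_corpus(merged, path)
        record("merge", path)
        return merged

    merged = run_stage("merge", _merge)

    # 4. embed
    def _embed():
        fps = fingerprint_corpus(
            merged, bits=config.bits, weighting=config.weighting, hash_seed=config.hash_seed
        )
        path = outdir / "fingerprints.csv"
        pd.DataFrame(
            {"note_ref": [fp.note_ref for fp in fps], "fingerprint": [fp.to_hex() for fp in fps]}
        ).to_csv(path, index=False)
        record("embed", path)
        return fps

    fps = run_stage("embed", _embed)

    # 5. cluster
    def _cluster():
        model = cluster_fingerprints(fps, k=config.k_clusters, seed=config.cluster_seed)
        path = outdir / "clusters.csv"
        rows = [
            {
                "note_ref": ref,
                "cluster": cl,
                "representative": model.representatives[cl] == ref,
            }
            for ref, cl in model.assignments.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
        record("cluster", path)
        return model

    run_stage("cluster", _cluster)

    # 6. align
    def _align():
        aligned = align_external(merged, anchor=config.anchor)
        path = outdir / "aligned.csv"
        pd.DataFrame(
            [
                {
                    "patient_id": a.note.patient_id,
                    "note_id": a.note.note_id,
                    "anchor": a.anchor,
                    "offset_hours": round(a.offset_hours, 4),
                }
                for a in aligned
            ]
        ).to_csv(path, index=False)
        record("align", path)

    run_stage("align", _align)

    # 7. reconstruct
    def _reconstruct():
        entities, model = reconstruct_corpus(
            merged,
            k_entities=config.k_entities,
            seed=config.medoid_seed,
            bits=config.bits,
            hash_seed=config.hash_seed,
        )
        db = build_sequences(entities, mode=config.mode)
        path = outdir / "sequences.jsonl"
        db.to_jsonl(path)
        db.to_frame("patient").to_csv(outdir / "sequences.csv", index=False)
        record("reconstruct", path)
        return db

    db = run_stage("reconstruct", _reconstruct)

    # 8. mine
    def _mine():
        mined = prefixspan(db, min_support=config.min_support, max_length=config.max_length)
        path = outdir / "patterns.csv"
        rows = top_k_report(mined, k=max(config.top, 1)) if mined else []
        pd.DataFrame(
            [{"freq": f, "pattern": json.dumps([str(i) for i in items])} for f, items in rows]
        ).to_csv(path, index=False)
        record("mine", path)

    run_stage("mine", _mine)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str), encoding="utf-8")
    return manifest


def _params_dict(config: RunConfig) -> dict:
    params = asdict(config)
    if params.get("synthetic") is not None:
        params["synthetic"] = {k: str(v) for k, v in params["synthetic"].items()}
    return params


def _truth_json(truth) -> str:
    return json.dumps(
        {
            "temporal": {
                f"{nid}:{line}": [[s, c, n] for s, c, n in exprs]
                for (nid, line), exprs in truth.temporal.items()
            },
            "duplicates": {f"{pid}:{nid}": line for (pid, nid), line in truth.duplicates.items()},
            "pattern_instances": [[pid, list(pat)] for pid, pat in truth.pattern_instances],
            "symptom_sequences": {
                pid: [[ts.isoformat(), s] for ts, s in seq]
                for pid, seq in truth.symptom_sequences.items()
            },
            "causes": truth.causes,
        },
        indent=1,
    )
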