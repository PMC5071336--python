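"""End-to-end orchestration: detect -> sequence -> syntax -> diagrams.

A study manifest lists one row per recording session (audio file or
pre-coded sequences table) with its animal, group, context and session
duration. The pipeline writes per-stage CSVs, per-comparison JSON results,
DOT diagrams and a machine-readable run report. Reruns skip the audio
stage for files whose content hash is unchanged from the previous report.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from usvsyntax import acoustics, sequencing, syntax_stats, syntax_viz

MANIFEST_COLUMNS = ["path", "kind", "animal_id", "group", "context", "session_minutes"]


@dataclass
class PipelineConfig:
    sonogram: acoustics.SonogramConfig = field(default_factory=acoustics.SonogramConfig)
    break_ms: float = sequencing.DEFAULT_BREAK_MS
    tau: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    fdr_family: str = "margins"
    diagram_cutoff: float = 0.05
    diagram_thickness: float = 10.0
    split_silence: bool = False
    # Comparisons are declared, not inferred, e.g.
    #   {"type": "two-sample", "context": "UF", "groups": ["WT", "HET"]}
    #   {"type": "paired", "group": "WT", "contexts": ["UF", "LF"]}
    comparisons: list[dict[str, Any]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        son = acoustics.SonogramConfig(**raw.pop("sonogram", {}))
        return cls(sonogram=son, **raw)


def load_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    dup = manifest.duplicated(subset=["animal_id", "context"])
    if dup.any():
        pairs = manifest.loc[dup, ["animal_id", "context"]].values.tolist()
        raise ValueError(f"duplicate (animal_id, context) sessions: {pairs}")
    return manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _detect_stage(
    manifest: pd.DataFrame,
    config: PipelineConfig,
    outdir: Path,
    base_dir: Path,
    prev_hashes: dict[str, str],
    log,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Syllable events for every session, as one long table."""
    syl_dir = outdir / "syllables"
    syl_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    hashes: dict[str, str] = {}
    for row in manifest.itertuples():
        path = base_dir / row.path
        if not path.exists():
            raise FileNotFoundError(f"manifest references missing file: {path}")
        out_csv = syl_dir / f"{row.animal_id}_{row.context}.csv"
        if row.kind == "audio":
            digest = _sha256(path)
            hashes[str(row.path)] = digest
            if out_csv.exists() and prev_hashes.get(str(row.path)) == digest:
                log(f"detect: {row.path} unchanged, reusing {out_csv.name}")
                table = pd.read_csv(out_csv)
            else:
                t0 = time.perf_counter()
                rate, wave = acoustics.read_wav(path)
                events = acoustics.analyze_waveform(wave, rate, config.sonogram)
                table = acoustics.events_to_table(events, file=str(row.path))
                table.to_csv(out_csv, index=False)
                log(
                    f"detect: {row.path}: {len(table)} syllables "
                    f"({time.perf_counter() - t0:.2f} s)"
                )
        elif row.kind == "syllables":
            table = pd.read_csv(path)
        else:
            raise ValueError(f"unknown manifest kind {row.kind!r} for {row.path}")
        table = table.copy()
        table["animal_id"] = row.animal_id
        table["group"] = row.group
        table["context"] = row.context
        table["session_minutes"] = row.session_minutes
        frames.append(table)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return out, hashes


def _sequence_stage(
    syllables: pd.DataFrame, config: PipelineConfig, outdir: Path, log
) -> tuple[pd.DataFrame, pd.DataFrame]:
    seq_rows = []
    summary_rows = []
    for (animal, group, ctx), sess in syllables.groupby(
        ["animal_id", "group", "context"], sort=True
    ):
        sess = sess.sort_values("onset_s")
        keep = sess[sess["label"].isin(sequencing.SYLLABLE_LABELS)]
        seqs = sequencing.segment_into_sequences(
            keep["label"].tolist(),
            keep["onset_s"].to_numpy(),
            keep["offset_s"].to_numpy(),
            break_ms=config.break_ms,
            animal_id=str(animal),
            context=str(ctx),
        )
        table = sequencing.sequences_to_table(seqs)
        table["group"] = group
        seq_rows.append(table)
        summary = sequencing.session_summary(
            keep["label"].tolist(),
            seqs,
            float(sess["session_minutes"].iloc[0]),
            animal_id=str(animal),
            context=str(ctx),
        )
        summary_rows.append(
            {
                "animal_id": animal,
                "group": group,
                "context": ctx,
                "session_minutes": summary.session_minutes,
                "total_syllables": summary.total_syllables,
                "syllable_rate_per_min": summary.syllable_rate_per_min,
                **{f"prop_{k}": v for k, v in summary.repertoire.items()},
                "n_sequences": summary.n_sequences,
                "mean_sequence_length": summary.mean_sequence_length,
                "complex_simple_ratio": summary.complex_simple_ratio,
            }
        )
    sequences = (
        pd.concat(seq_rows, ignore_index=True) if seq_rows else pd.DataFrame()
    )
    summaries = pd.DataFrame(summary_rows)
    sequences.to_csv(outdir / "sequences.csv", index=False)
    summaries.to_csv(outdir / "summaries.csv", index=False)
    log(f"sequence: {len(sequences)} bouts across {len(summaries)} sessions")
    return sequences, summaries


def matrices_by_group_context(
    sequences: pd.DataFrame,
) -> dict[tuple[str, str], dict[str, np.ndarray]]:
    """Per (group, context): animal -> conditional probability matrix."""
    out: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for (group, ctx, animal), rows in sequences.groupby(
        ["group", "context", "animal_id"], sort=True
    ):
        coded = [s for s in rows["coded_string"].astype(str) if s]
        counts = syntax_stats.transition_counts(coded, str(animal), str(ctx))
        out.setdefault((str(group), str(ctx)), {})[str(animal)] = (
            syntax_stats.conditional_probabilities(counts)
        )
    return out


def _syntax_stage(
    sequences: pd.DataFrame, config: PipelineConfig, outdir: Path, log
) -> list[dict[str, Any]]:
    mats = matrices_by_group_context(sequences)
    results_dir = outdir / "syntax"
    results_dir.mkdir(exist_ok=True)
    report = []
    for k, comp in enumerate(config.comparisons):
        seed = config.seed + k
        if comp["type"] == "two-sample":
            ctx = comp["context"]
            g1, g2 = comp["groups"]
            for g in (g1, g2):
                if (g, ctx) not in mats or not mats[(g, ctx)]:
                    raise ValueError(f"no animals for group {g!r} in context {ctx!r}")
            name = f"{g1}_vs_{g2}_{ctx}"
            res = syntax_stats.compare_two_sample(
                list(mats[(g1, ctx)].values()),
                list(mats[(g2, ctx)].values()),
                n_perm=config.n_perm,
                seed=seed,
                tau=config.tau,
                fdr_family=config.fdr_family,
                comparison=name,
            )
        elif comp["type"] == "paired":
            g = comp["group"]
            c1, c2 = comp["contexts"]
            for c in (c1, c2):
                if (g, c) not in mats or not mats[(g, c)]:
                    raise ValueError(f"no animals for group {g!r} in context {c!r}")
            a1, a2 = mats[(g, c1)], mats[(g, c2)]
            shared = sorted(set(a1) & set(a2))
            if not shared:
                raise ValueError(f"no shared animals between contexts {c1!r}/{c2!r}")
            name = f"{g}_{c1}_vs_{c2}"
            res = syntax_stats.compare_paired(
                [a1[a] for a in shared],
                [a2[a] for a in shared],
                n_perm=config.n_perm,
                seed=seed,
                tau=config.tau,
                fdr_family=config.fdr_family,
                comparison=name,
                animal_ids_a=shared,
                animal_ids_b=shared,
            )
        else:
            raise ValueError(f"unknown comparison type {comp['type']!r}")
        payload = res.to_json_dict()
        (results_dir / f"{name}.json").write_text(json.dumps(payload, indent=2))
        syntax_stats.heatmap_table(res).to_csv(results_dir / f"{name}_heatmap.csv")
        log(f"syntax: {name}: global p = {res.global_p}")
        report.append({"name": name, "seed": seed, **comp, "global_p": payload["global_p"]})
    return report


def _diagram_stage(
    sequences: pd.DataFrame, config: PipelineConfig, outdir: Path, log
) -> list[str]:
    dot_dir = outdir / "diagrams"
    dot_dir.mkdir(exist_ok=True)
    written = []
    for (group, ctx), animals in sorted(matrices_by_group_context(sequences).items()):
        mean, _ = syntax_stats.group_mean_probabilities(list(animals.values()))
        dot = syntax_viz.to_dot(
            mean,
            cutoff=config.diagram_cutoff,
            thickness_scale=config.diagram_thickness,
            split_silence=config.split_silence,
            name=f"{group}_{ctx}",
        )
        path = dot_dir / f"{group}_{ctx}.dot"
        path.write_text(dot)
        written.append(path.name)
    log(f"diagram: wrote {len(written)} DOT files")
    return written


def run_pipeline(
    manifest: pd.DataFrame | str | Path,
    config: PipelineConfig,
    outdir: str | Path,
    base_dir: str | Path | None = None,
    log=None,
) -> dict[str, Any]:
    """Run every stage and return (and write) the run report."""
    log = log or (lambda msg: None)
    if not isinstance(manifest, pd.DataFrame):
        base_dir = base_dir or Path(manifest).parent
        manifest = load_manifest(manifest)
    base_dir = Path(base_dir) if base_dir is not None else Path(".")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for comp in config.comparisons:
        groups = comp.get("groups", [comp.get("group")])
        for g in groups:
            if g not in set(manifest["group"].astype(str)):
                raise ValueError(f"comparison references unknown group {g!r}")
    report_path = outdir / "run_report.json"
    prev_hashes: dict[str, str] = {}
    if report_path.exists():
        try:
            prev_hashes = json.loads(report_path.read_text()).get("input_hashes", {})
        except (json.JSONDecodeError, OSError):
            prev_hashes = {}
    syllables, hashes = _detect_stage(
        manifest, config, outdir, base_dir, prev_hashes, log
    )
    syllables.to_csv(outdir / "syllables.csv", index=False)
    sequences, _ = _sequence_stage(syllables, config, outdir, log)
    comparisons = _syntax_stage(sequences, config, outdir, log)
    diagrams = _diagram_stage(sequences, config, outdir, log)
    report = {
        "seed": config.seed,
        "n_permutations": config.n_perm,
        "tau": config.tau,
        "comparisons": comparisons,
        "diagrams": diagrams,
        "input_hashes": hashes,
        "n_sessions": int(len(manifest)),
        "n_syllables": int(len(syllables)),
        "n_sequences": int(len(sequences)),
    }
    report_path.write_text(json.dumps(report, indent=2))
    return report
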