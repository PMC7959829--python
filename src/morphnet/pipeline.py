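"""End-to-end orchestration: vertex tables -> similarity -> OMST ->
efficiency -> interaction statistics, with a manifest of every artifact.

The pipeline is a pure function of (inputs, config): no stage mutates an
upstream artifact, and re-running the same config reproduces every output
digest byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from morphnet.efficiency import efficiency_profile
from morphnet.errors import MorphnetError, ValidationError
from morphnet.morphometry_io import filter_parcels, read_vertex_table
from morphnet.omst import absolutize, omst_select
from morphnet.similarity import build_similarity_matrix
from morphnet.stats import interaction_family, loo_reproducibility


@dataclass
class RunConfig:
    """Every knob of one pipeline run; serialized into the output directory."""

    vertex_table: str
    cohort_table: str
    out_dir: str
    measures: tuple[str, ...] = ("area",)
    behaviors: tuple[str, ...] = ("beh",)
    n_bins: int = 30
    min_vertices: int = 50
    omst_distance: str = "inverse"
    fdr_q: float = 0.05
    # FDR families: nodal/local across parcels per (measure, behavior,
    # metric); global across behaviors per measure.
    loo: bool = False
    loo_alpha: float = 0.05
    loo_scope: str = "significant"  # significant | all | global
    age_split: float = 35.0
    standardize: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("measures", "behaviors"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["measures"] = list(d["measures"])
        d["behaviors"] = list(d["behaviors"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class RunResult:
    """What a pipeline run produced, with content digests for reproducibility."""

    out_dir: Path
    results: pd.DataFrame
    manifest: pd.DataFrame
    n_subjects: int = 0
    artifacts: dict[str, Path] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_matrix(mat: np.ndarray, labels, path: Path) -> None:
    pd.DataFrame(mat, index=list(labels), columns=list(labels)).to_csv(path, sep="\t")


def _stage(name: str, subject: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except MorphnetError as exc:
        raise type(exc)(f"stage {name!r}, subject {subject!r}: {exc}") from exc


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full chain and write all artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    subjects = read_vertex_table(config.vertex_table)
    cohort = pd.read_csv(config.cohort_table, sep="\t", dtype={"subject_id": str})
    cohort = cohort.set_index("subject_id", drop=False)

    written: list[Path] = []
    results_rows = []
    for measure in config.measures:
        eff_frames = []
        e_global = {}
        morph_global = {}
        nodal_wide = {}
        local_wide = {}
        for sid, sm_raw in subjects.items():
            sm = _stage("filter_parcels", sid, filter_parcels, sm_raw, config.min_vertices)
            sim = _stage(
                "similarity", sid, build_similarity_matrix, sm, measure, config.n_bins
            )
            mpath = out / f"similarity_{measure}_{sid}.tsv"
            _write_matrix(sim.matrix, sim.labels, mpath)
            written.append(mpath)

            bg, diag = _stage(
                "omst", sid, omst_select, absolutize(sim), None, config.omst_distance
            )
            apath = out / f"adjacency_{measure}_{sid}.tsv"
            _write_matrix(bg.adjacency, bg.labels, apath)
            written.append(apath)
            dpath = out / f"omst_diagnostics_{measure}_{sid}.tsv"
            diag.table.to_csv(dpath, sep="\t", index=False)
            written.append(dpath)

            prof = efficiency_profile(bg, subject_id=sid, measure=measure)
            eff_frames.append(prof.to_frame())
            e_global[sid] = prof.e_global
            morph_global[sid] = sm.global_summary(measure)
            nodal_wide[sid] = dict(zip(prof.labels, prof.e_nodal))
            local_wide[sid] = dict(zip(prof.labels, prof.e_local))

        eff_long = pd.concat(eff_frames, ignore_index=True)
        epath = out / f"efficiency_{measure}.tsv"
        eff_long.to_csv(epath, sep="\t", index=False)
        written.append(epath)

        analysis = cohort.copy()
        analysis["morph_global"] = analysis["subject_id"].map(morph_global)
        analysis["e_global"] = analysis["subject_id"].map(e_global)
        if analysis[["morph_global", "e_global"]].isna().any().any():
            missing = analysis.index[analysis["e_global"].isna()].tolist()
            raise ValidationError(
                f"cohort subjects absent from vertex table: {missing}"
            )
        parcels = sorted({p for d in nodal_wide.values() for p in d})
        for p in parcels:
            analysis[f"nodal::{p}"] = analysis["subject_id"].map(
                {s: d[p] for s, d in nodal_wide.items()}
            )
            analysis[f"local::{p}"] = analysis["subject_id"].map(
                {s: d[p] for s, d in local_wide.items()}
            )

        # age-group scatter export for the subgroup visualizations
        scatter = analysis[
            ["subject_id", "age", "e_global", *config.behaviors]
        ].copy()
        scatter["age_group"] = np.where(
            analysis["age"] < config.age_split, "young", "middle-aged"
        )
        spath = out / f"scatter_{measure}.tsv"
        scatter.to_csv(spath, sep="\t", index=False)
        written.append(spath)

        results_rows.extend(
            _measure_stats(analysis, measure, parcels, config)
        )

    results = pd.DataFrame(results_rows)
    rpath = out / "results.tsv"
    results.to_csv(rpath, sep="\t", index=False)
    written.append(rpath)
    written.append(out / "config.yaml")

    manifest = pd.DataFrame(
        [{"artifact": p.name, "sha256": _sha256(p)} for p in sorted(written)]
    )
    mpath = out / "manifest.tsv"
    manifest.to_csv(mpath, sep="\t", index=False)

    return RunResult(
        out_dir=out,
        results=results,
        manifest=manifest,
        n_subjects=len(subjects),
        artifacts={p.name: p for p in written},
    )


def _measure_stats(
    analysis: pd.DataFrame, measure: str, parcels: list[str], config: RunConfig
) -> list[dict]:
    """Interaction fits + FDR + optional LOO for one network measure."""
    rows: list[dict] = []

    def emit(frame: pd.DataFrame, metric: str) -> None:
        for _, r in frame.iterrows():
            col = r["efficiency_column"]
            parcel = col.split("::", 1)[1] if "::" in col else "global"
            do_loo = config.loo and (
                config.loo_scope == "all"
                or (config.loo_scope == "global" and metric == "global")
                or (config.loo_scope == "significant" and bool(r["significant"]))
            )
            repro = float("nan")
            if do_loo:
                loo = loo_reproducibility(
                    analysis,
                    r["behavior"],
                    col,
                    alpha=config.loo_alpha,
                    standardize=config.standardize,
                )
                repro = loo.reproducibility_pct
            rows.append(
                {
                    "measure": measure,
                    "metric": metric,
                    "parcel": parcel,
                    "behavior": r["behavior"],
                    "beta": r["beta"],
                    "t": r["t"],
                    "p": r["p"],
                    "q": r["q"],
                    "significant": bool(r["significant"]),
                    "reproducibility_pct": repro,
                    "n": int(r["n"]),
                }
            )

    # global efficiency: one test per behavior, FDR across behaviors
    from morphnet.stats import fdr_bh, fit_interaction_glm

    fits = [
        fit_interaction_glm(analysis, beh, "e_global", standardize=config.standardize)
        for beh in config.behaviors
    ]
    fdr = fdr_bh([f.p_value for f in fits], config.fdr_q, family=f"{measure}:global")
    gframe = pd.DataFrame(
        {
            "behavior": list(config.behaviors),
            "efficiency_column": "e_global",
            "beta": [f.beta for f in fits],
            "t": [f.t_stat for f in fits],
            "p": [f.p_value for f in fits],
            "q": fdr.q_values,
            "significant": fdr.significant,
            "n": [f.n for f in fits],
        }
    )
    emit(gframe, "global")

    # nodal / local: FDR across parcels within (measure, behavior, metric)
    for metric, prefix in (("nodal", "nodal::"), ("local", "local::")):
        cols = [f"{prefix}{p}" for p in parcels]
        usable = [
            c for c in cols if analysis[c].std() > 0
        ]  # all-zero local efficiency columns carry no signal to test
        for beh in config.behaviors:
            frame = interaction_family(
                analysis,
                beh,
                usable,
                q_threshold=config.fdr_q,
                standardize=config.standardize,
            )
            emit(frame, metric)
    return rows
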