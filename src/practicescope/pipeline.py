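"""End-to-end study pipeline: generate -> score -> ecg -> aggregate -> analyze.

Each stage reads files written by earlier stages, so a run is resumable
and individual stages can be re-executed from the CLI.  Stage outputs are
cached: a stage whose inputs (file hashes + its parameter block) are
unchanged is skipped on re-run.  With a fixed seed the whole run is
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ecg as ecg_mod
from . import midi_scoring, models, quality, synth
from .score import TargetScore, load_score

log = logging.getLogger("practicescope")

STAGES = ("generate", "score", "ecg", "aggregate", "analyze")
FLOAT_FMT = "%.10g"

ANXIETY_VARS = ("stai_t", "stai_s", "vasa1", "vasa2", "vasa3", "vasa4",
                "mean_hr_bpm", "cvrr_pct", "slope_hr_bpm_per_min")
PRACTICE_VARS = ("practice_time_min", "total_keystrokes", "keystrokes_on_target")


@dataclass
class RunConfig:
    study_dir: Path
    out_dir: Path | None = None
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    n_participants: int = 30
    include_ecg: bool = True
    gap_threshold: float = midi_scoring.DEFAULT_GAP_THRESHOLD_S
    cutoff_hz: float = ecg_mod.DEFAULT_CUTOFF_HZ
    fs_out_hz: float = ecg_mod.DEFAULT_FS_OUT_HZ
    retention_threshold: float = quality.RETENTION_THRESHOLD
    anxiety_models: tuple[str, ...] = ("vasa1", "vasa2")
    lcs_zero_constraints: tuple[tuple[str, str], ...] = (("perf1", "dvasa_pre"),)
    mixed_spec: models.MixedModelSpec = field(default_factory=models.MixedModelSpec)

    def __post_init__(self) -> None:
        self.study_dir = Path(self.study_dir)
        self.out_dir = Path(self.out_dir) if self.out_dir else self.study_dir / "results"
        order = {s: i for i, s in enumerate(STAGES)}
        unknown = [s for s in self.stages if s not in order]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        self.stages = tuple(sorted(set(self.stages), key=order.get))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "lcs_zero_constraints" in raw:
            raw["lcs_zero_constraints"] = tuple(tuple(p) for p in raw["lcs_zero_constraints"])
        if "mixed_spec" in raw:
            raw["mixed_spec"] = models.MixedModelSpec(**raw["mixed_spec"])
        if "anxiety_models" in raw:
            raw["anxiety_models"] = tuple(raw["anxiety_models"])
        return cls(**raw)

    def jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_dir"], d["out_dir"] = str(self.study_dir), str(self.out_dir)
        return d


@dataclass
class RunReport:
    stage_status: dict  # stage -> "ok" | "cached" | "skipped"
    output_hashes: dict  # filename -> sha256
    headline: dict
    config: dict
    version: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_inputs(paths: list[Path], params: dict) -> str:
    h = hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode())
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(_sha256(p).encode())
    return h.hexdigest()


def read_study(study_dir: str | Path, load_ecg: bool = False):
    """Load and validate a study tree.

    Returns ``(score, participants, questionnaires, excluded)`` where
    ``participants`` maps id -> dict of recordings and ``excluded`` lists
    participants dropped for missing files (listwise exclusion policy).
    Raises ``ValueError`` listing offending rows on invariant violations.
    """
    study_dir = Path(study_dir)
    score = load_score(study_dir / "target_score.json")
    questionnaires = pd.read_csv(study_dir / "questionnaires.csv")

    problems = []
    for col in ("vasa1", "vasa2", "vasa3", "vasa4"):
        bad = questionnaires[~questionnaires[col].between(0, 10)]
        problems += [f"{r.id}: {col}={getattr(r, col)} outside 0-10" for r in bad.itertuples()]
    for col in ("stai_t", "stai_s"):
        bad = questionnaires[~questionnaires[col].between(20, 80)]
        problems += [f"{r.id}: {col}={getattr(r, col)} outside 20-80" for r in bad.itertuples()]
    if problems:
        raise ValueError("questionnaire validation failed:\n" + "\n".join(problems))

    participants, excluded = {}, []
    for pid in questionnaires["id"]:
        pdir = study_dir / str(pid)
        needed = [pdir / f"{ph}.mid" for ph in ("baseline", "acquisition", "practice")]
        if not all(f.exists() for f in needed):
            log.warning("participant %s incomplete; excluded listwise", pid)
            excluded.append(str(pid))
            continue
        rec = {
            ph: midi_scoring.load_recording(pdir / f"{ph}.mid", ph, str(pid))
            for ph in ("baseline", "acquisition", "practice")
        }
        if load_ecg and (pdir / "ecg.csv").exists():
            rec["ecg"] = ecg_mod.read_ecg_csv(pdir / "ecg.csv")
        participants[str(pid)] = rec
    return score, participants, questionnaires, excluded


# ---------------------------------------------------------------------------
# stages


def stage_generate(cfg: RunConfig) -> None:
    scfg = synth.SynthConfig(
        n_participants=cfg.n_participants, include_ecg=cfg.include_ecg, seed=cfg.seed
    )
    synth.generate_study(scfg, out_dir=cfg.study_dir)


def stage_score(cfg: RunConfig) -> None:
    score = load_score(cfg.study_dir / "target_score.json")
    df = midi_scoring.assess_study(cfg.study_dir, score, cfg.gap_threshold)
    assessments = df[df.phase.isin(["baseline", "acquisition"])].dropna(axis=1, how="all")
    practice = df[df.phase == "practice"].dropna(axis=1, how="all")
    assessments.to_csv(cfg.out_dir / "assessments.csv", index=False, float_format=FLOAT_FMT)
    practice.to_csv(cfg.out_dir / "practice.csv", index=False, float_format=FLOAT_FMT)


def stage_ecg(cfg: RunConfig) -> None:
    df = ecg_mod.process_study(cfg.study_dir, cutoff=cfg.cutoff_hz, fs_out=cfg.fs_out_hz)
    df.to_csv(cfg.out_dir / "cardiac.csv", index=False, float_format=FLOAT_FMT)


def stage_aggregate(cfg: RunConfig) -> None:
    """Fit the quality composite and join every per-participant table."""
    assessments = pd.read_csv(cfg.out_dir / "assessments.csv")
    model = quality.fit_quality_component(assessments, retention_threshold=cfg.retention_threshold)
    scores = quality.quality_scores(model, assessments, unit_variance=True)
    scores.to_csv(cfg.out_dir / "quality.csv", index=False, float_format=FLOAT_FMT)
    model.to_json(cfg.out_dir / "quality_model.json")

    practice = pd.read_csv(cfg.out_dir / "practice.csv")
    questionnaires = pd.read_csv(cfg.study_dir / "questionnaires.csv")
    wide = questionnaires.merge(
        practice[["id", "practice_time_min", "keystrokes_on_target", "total_keystrokes"]],
        on="id", how="inner",
    )
    piv = scores.pivot(index="id", columns="phase", values="score").reset_index()
    piv.columns.name = None
    wide = wide.merge(piv.rename(columns={"baseline": "perf1", "acquisition": "perf2"}),
                      on="id", how="inner")
    cardiac_path = cfg.out_dir / "cardiac.csv"
    if cardiac_path.exists():
        cardiac = pd.read_csv(cardiac_path)
        wide = wide.merge(cardiac.drop(columns=["phase"]), on="id", how="left")
    wide.to_csv(cfg.out_dir / "dataset.csv", index=False, float_format=FLOAT_FMT)


def stage_analyze(cfg: RunConfig) -> dict:
    wide = pd.read_csv(cfg.out_dir / "dataset.csv")
    headline: dict = {}

    anx_vars = [v for v in ANXIETY_VARS if v in wide.columns and wide[v].notna().all()]
    corr = models.correlation_matrix(wide, anx_vars, list(PRACTICE_VARS))
    corr.pairs.to_csv(cfg.out_dir / "table2.csv", index=False, float_format=FLOAT_FMT)
    headline["anxiety_practice_correlations"] = {
        f"{r.var_x}~{r.var_y}": round(r.r, 4) for r in corr.pairs.itertuples()
    }

    if "gender" in wide.columns and wide["gender"].nunique() == 2:
        gd = models.group_difference(wide["vasa1"], wide["gender"])
        headline["gender_vasa1_p"] = round(gd.p, 4)

    long_rows = []
    for r in wide.itertuples():
        long_rows.append(dict(id=r.id, time=0.0, score=r.perf1))
        long_rows.append(dict(id=r.id, time=r.practice_time_min, score=r.perf2))
    long = pd.DataFrame(long_rows).merge(
        wide[["id"] + list(cfg.anxiety_models)], on="id"
    )

    table3 = {}
    for i, anx in enumerate(cfg.anxiety_models):
        fit = models.fit_mixed_model(long, anx, cfg.mixed_spec, seed=cfg.seed + 1000 + i)
        table3[anx] = dict(
            fixed={
                n: dict(estimate=round(fit.estimate(n), 4),
                        ci=[round(v, 4) for v in fit.ci(n)],
                        meaningful=fit.meaningful[n])
                for n in models.FIXED_EFFECTS
            },
            random={
                n: dict(estimate=round(fit.estimate(n), 4),
                        ci=[round(v, 4) for v in fit.ci(n)])
                for n in models.VARIANCE_PARAMS
            },
            r2_conditional=[round(v, 4) for v in fit.r2_conditional],
            r2_marginal=[round(v, 4) for v in fit.r2_marginal],
            diagnostics={k: round(v, 4) for k, v in fit.diagnostics.items()},
            converged=fit.converged,
        )
    (cfg.out_dir / "table3.json").write_text(json.dumps(table3, indent=1, sort_keys=True))
    headline["mixed_models"] = {
        anx: {n: table3[anx]["fixed"][n]["estimate"] for n in models.FIXED_EFFECTS}
        for anx in table3
    }

    lcs_fit = models.fit_lcs(wide, models.LcsSpec(zero_constraints=cfg.lcs_zero_constraints))
    lcs_payload = dict(
        chi2=round(lcs_fit.chi2, 4), df=lcs_fit.df, p=round(lcs_fit.p, 4),
        cfi=round(lcs_fit.cfi, 4),
        tli=None if np.isnan(lcs_fit.tli) else round(lcs_fit.tli, 4),
        rfi=None if np.isnan(lcs_fit.rfi) else round(lcs_fit.rfi, 4),
        srmr=round(lcs_fit.srmr, 4),
        correlations=[
            {k: (None if isinstance(v, float) and np.isnan(v) else
                 (round(v, 4) if isinstance(v, float) else v))
             for k, v in row.items()}
            for row in lcs_fit.correlations.to_dict("records")
        ],
        n=lcs_fit.n,
    )
    (cfg.out_dir / "lcs.json").write_text(json.dumps(lcs_payload, indent=1, sort_keys=True))
    headline["lcs"] = {
        f"{r.component_a}~{r.component_b}": round(r.r, 4)
        for r in lcs_fit.correlations.itertuples()
    }
    headline["lcs_fit"] = {k: lcs_payload[k] for k in ("chi2", "df", "cfi", "srmr")}
    return headline


_STAGE_INPUTS = {
    "generate": lambda cfg: [],
    "score": lambda cfg: sorted(cfg.study_dir.glob("*/[ab]*.mid"))
    + sorted(cfg.study_dir.glob("*/practice.mid")) + [cfg.study_dir / "target_score.json"],
    "ecg": lambda cfg: sorted(cfg.study_dir.glob("*/ecg.csv")),
    "aggregate": lambda cfg: [
        p for p in (cfg.out_dir / "assessments.csv", cfg.out_dir / "practice.csv",
                    cfg.out_dir / "cardiac.csv", cfg.study_dir / "questionnaires.csv")
        if p.exists()
    ],
    "analyze": lambda cfg: [cfg.out_dir / "dataset.csv"],
}

_STAGE_OUTPUTS = {
    "generate": ("questionnaires.csv",),
    "score": ("assessments.csv", "practice.csv"),
    "ecg": ("cardiac.csv",),
    "aggregate": ("quality.csv", "quality_model.json", "dataset.csv"),
    "analyze": ("table2.csv", "table3.json", "lcs.json"),
}

_STAGE_FN = {
    "generate": stage_generate,
    "score": stage_score,
    "ecg": stage_ecg,
    "aggregate": stage_aggregate,
    "analyze": stage_analyze,
}


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the configured stages in order with hash-based caching."""
    from . import __version__

    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    cache_file = cfg.out_dir / ".stage_hashes.json"
    cache = json.loads(cache_file.read_text()) if cache_file.exists() else {}
    status: dict = {}
    headline: dict = {}
    params = cfg.jsonable()

    for stage in STAGES:
        if stage not in cfg.stages:
            status[stage] = "skipped"
            continue
        out_paths = [
            (cfg.study_dir if stage == "generate" else cfg.out_dir) / f
            for f in _STAGE_OUTPUTS[stage]
        ]
        inputs = _STAGE_INPUTS[stage](cfg)
        key = _hash_inputs(inputs, {**params, "stage": stage})
        if cache.get(stage) == key and all(p.exists() for p in out_paths):
            log.info("stage %s: cached", stage)
            status[stage] = "cached"
            if stage == "analyze":
                headline = json.loads((cfg.out_dir / "headline.json").read_text())
            continue
        log.info("stage %s: running", stage)
        try:
            result = _STAGE_FN[stage](cfg)
        except Exception as exc:  # partial outputs retained for inspection
            status[stage] = "failed"
            raise StageError(stage, exc) from exc
        if stage == "analyze":
            headline = result or {}
            (cfg.out_dir / "headline.json").write_text(
                json.dumps(headline, indent=1, sort_keys=True)
            )
        # re-key on the actual post-run inputs (generate creates its inputs)
        cache[stage] = _hash_inputs(_STAGE_INPUTS[stage](cfg), {**params, "stage": stage})
        cache_file.write_text(json.dumps(cache, indent=1, sort_keys=True))
        status[stage] = "ok"

    hashes = {}
    for stage in cfg.stages:
        d = cfg.study_dir if stage == "generate" else cfg.out_dir
        for f in _STAGE_OUTPUTS[stage]:
            if (d / f).exists():
                hashes[f] = _sha256(d / f)
    report = RunReport(
        stage_status=status, output_hashes=hashes, headline=headline,
        config=params, version=__version__,
    )
    report.to_json(cfg.out_dir / "report.json")
    return report
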