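"""End-to-end pipeline: population -> sensitivity screen -> Monte Carlo ->
regression report, with CSV stage interfaces and full seed provenance.

Stages communicate only through their documented CSV files, so any stage can
be re-run or inspected in isolation.  A run manifest (JSON) records the
config hash, master seed, per-stage outputs and wall-clock times; the same
config + seed reproduces the same outputs (the manifest hash excludes
timings).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .params import ModelParams, default_params, load_config
from .population import (
    draw_exposure_profile,
    draw_subjects,
    exposures_from_csv,
    exposures_to_csv,
    subjects_from_csv,
    subjects_to_csv,
)
from .regression import qualitative_flags, report, run_all_analyses
from .sensitivity import (
    monte_carlo,
    panels_to_frame,
    sensitivity_screen,
    sensitivity_to_frame,
)

log = logging.getLogger("carbarylsim")

#: (n_subjects, n_reps) presets; "full" matches the 500 x 10 study design,
#: "desk" is the scaled-down profile exercising the identical code path
PROFILES = {"full": (500, 10), "desk": (50, 2), "smoke": (6, 1)}


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    version: str
    n_subjects: int
    n_reps: int
    outputs: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    qualitative_flags: dict[str, bool] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _config_hash(params: ModelParams) -> str:
    payload = json.dumps(params.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _seed_for(master_seed: int, stage: int) -> int:
    return int(
        np.random.SeedSequence([int(master_seed), 100 + stage]).generate_state(1)[0]
        % (2**31)
    )


def stage_popgen(outdir: Path, seed: int, n_subjects: int) -> dict[str, Path]:
    subjects = draw_subjects(n_subjects, seed=seed)
    profiles = [draw_exposure_profile(s, seed=seed) for s in subjects]
    paths = {"subjects": outdir / "subjects.csv", "exposures": outdir / "exposures.csv"}
    subjects_to_csv(subjects, paths["subjects"])
    exposures_to_csv(profiles, paths["exposures"])
    return paths


def stage_sens(outdir: Path, params: ModelParams) -> dict[str, Path]:
    records = sensitivity_screen(params)
    path = outdir / "sensitivity.csv"
    sensitivity_to_frame(records).to_csv(path, index=False)
    return {"sensitivity": path}


def stage_mc(
    outdir: Path, params: ModelParams, seed: int, n_reps: int
) -> dict[str, Path]:
    subjects = subjects_from_csv(outdir / "subjects.csv")
    profiles = exposures_from_csv(outdir / "exposures.csv")
    records = monte_carlo(params, subjects, reps=n_reps, seed=seed, profiles=profiles)
    failed = [r for r in records if r.error is not None]
    for r in failed:
        log.warning("iteration (subject=%s, rep=%s) failed: %s", r.subject_id, r.rep, r.error)
    path = outdir / "panels.csv"
    panels_to_frame(records).to_csv(path, index=False)
    return {"panels": path}


def stage_analyze(outdir: Path, dose_floor: float = 50.0) -> tuple[dict[str, Path], dict[str, bool]]:
    import pandas as pd

    panels = pd.read_csv(outdir / "panels.csv")
    results = run_all_analyses(panels, dose_floor=dose_floor)
    written = report(results, panels, outdir)
    flags = qualitative_flags(results)
    return {p.stem: p for p in written}, flags


def run_all(
    config_path: str | Path | None,
    outdir: str | Path,
    master_seed: int,
    profile: str = "desk",
    n_subjects: int | None = None,
    n_reps: int | None = None,
    dose_floor: float = 50.0,
    resume: bool = False,
) -> RunManifest:
    """Execute every stage in order and return the run manifest.

    ``profile`` picks a (subjects, reps) preset unless explicit counts are
    given.  With ``resume``, stages whose outputs already exist are skipped.
    """
    params = load_config(config_path) if config_path else default_params()
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    ns, nr = PROFILES[profile]
    ns = n_subjects if n_subjects is not None else ns
    nr = n_reps if n_reps is not None else nr

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(params),
        master_seed=int(master_seed),
        version=__version__,
        n_subjects=ns,
        n_reps=nr,
    )

    def run_stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        skip = resume and all(
            (outdir / f).exists() for f in _STAGE_OUTPUTS[name]
        )
        if skip:
            log.info("stage %s: outputs present, skipped (resume)", name)
            paths = {f: outdir / f for f in _STAGE_OUTPUTS[name]}
        else:
            log.info("stage %s: starting", name)
            try:
                paths = fn(*args, **kwargs)
            except Exception:
                manifest.write(outdir / "manifest.json")
                log.exception("stage %s failed; partial outputs kept in %s", name, outdir)
                raise
        manifest.timings_s[name] = round(time.perf_counter() - t0, 3)
        if isinstance(paths, dict):
            manifest.outputs.update({k: str(v) for k, v in paths.items()})
        return paths

    run_stage("popgen", stage_popgen, outdir, _seed_for(master_seed, 1), ns)
    run_stage("sens", stage_sens, outdir, params)
    run_stage("mc", stage_mc, outdir, params, _seed_for(master_seed, 2), nr)
    t0 = time.perf_counter()
    written, flags = stage_analyze(outdir, dose_floor=dose_floor)
    manifest.timings_s["analyze"] = round(time.perf_counter() - t0, 3)
    manifest.outputs.update({k: str(v) for k, v in written.items()})
    manifest.qualitative_flags = flags

    manifest.write(outdir / "manifest.json")
    missing = [p for p in manifest.outputs.values() if not Path(p).exists()]
    if missing:
        raise RuntimeError(f"manifest lists missing outputs: {missing}")
    return manifest


_STAGE_OUTPUTS = {
    "popgen": ("subjects.csv", "exposures.csv"),
    "sens": ("sensitivity.csv",),
    "mc": ("panels.csv",),
}
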