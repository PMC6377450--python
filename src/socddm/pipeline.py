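"""Canonical file formats, run configuration and the end-to-end recovery
study.

The canonical trial table is a CSV with one row per trial and columns::

    participant, group, block, disparity_deg, disparity_norm, advice,
    advice_correct, response, rt_s, conformed, excluded, exclude_reason

Excluded rows are preserved on disk (audit trail) and skipped by the
analysis loaders.  RTs are stored in seconds with 12 significant digits so
that threshold comparisons (e.g. the 8 s exclusion rule) survive a
round trip.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (GroupProfile, apply_exclusions, default_profiles,
                     generate_cohort, preset_profile)

__all__ = ["TRIAL_COLUMNS", "read_trials", "write_trials", "RunConfig",
           "run_simulation", "recovery_study"]

TRIAL_COLUMNS = ["participant", "group", "block", "disparity_deg",
                 "disparity_norm", "advice", "advice_correct", "response",
                 "rt_s", "conformed", "excluded", "exclude_reason"]

_REQUIRED = set(TRIAL_COLUMNS) - {"excluded", "exclude_reason", "advice_correct",
                                  "conformed"}


class TrialSchemaError(ValueError):
    pass


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write the canonical trial CSV (all rows, including flagged ones)."""
    t = trials.copy()
    for c in ("excluded",):
        if c not in t.columns:
            t[c] = False
    for c in ("exclude_reason",):
        if c not in t.columns:
            t[c] = ""
    cols = [c for c in TRIAL_COLUMNS if c in t.columns]
    extra = [c for c in t.columns if c not in TRIAL_COLUMNS and c != "terminated"]
    t[cols + (["terminated"] if "terminated" in t.columns else []) + extra] \
        .to_csv(path, index=False, float_format="%.12g")


def read_trials(path, keep_excluded: bool = False) -> pd.DataFrame:
    """Read a canonical trial CSV, validating the schema.

    Missing required columns raise :class:`TrialSchemaError` naming the
    column; unknown columns are kept with a warning attribute.  By default
    rows flagged ``excluded`` are dropped (they remain on disk).
    """
    t = pd.read_csv(path)
    missing = _REQUIRED - set(t.columns)
    if missing:
        raise TrialSchemaError(f"missing required column(s): {sorted(missing)}")
    unknown = [c for c in t.columns if c not in TRIAL_COLUMNS + ["terminated"]]
    t.attrs["unknown_columns"] = unknown
    if "excluded" not in t.columns:
        t["excluded"] = False
    if "exclude_reason" not in t.columns:
        t["exclude_reason"] = ""
    t["exclude_reason"] = t["exclude_reason"].fillna("")
    for c in ("advice", "response", "group"):
        if c in t.columns:
            t[c] = t[c].astype("category")
    if "conformed" in t.columns:
        t["conformed"] = t["conformed"].astype("boolean")
    if "advice_correct" in t.columns:
        t["advice_correct"] = t["advice_correct"].astype("boolean")
    if not keep_excluded:
        t = t.loc[~t["excluded"].astype(bool)].reset_index(drop=True)
    return t


@dataclass
class RunConfig:
    """Fully serializable description of one reproducible run."""
    seed: int = 0
    advisor: str = "adult"
    profiles: list = field(default_factory=list)   # list of GroupProfile or dicts
    apply_exclusions: bool = True
    quantile_probs: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    n_restarts: int = 5
    n_boot: int = 1000
    n_perm: int = 2000
    strict_disparity_tying: bool = False
    out_dir: str = "socddm_out"

    def resolved_profiles(self) -> list[GroupProfile]:
        if not self.profiles:
            return default_profiles(self.advisor)
        out = []
        for p in self.profiles:
            if isinstance(p, GroupProfile):
                out.append(p)
            elif isinstance(p, str):
                out.append(preset_profile(p, self.advisor))
            else:
                out.append(GroupProfile(**p))
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["profiles"] = [dataclasses.asdict(p) if isinstance(p, GroupProfile) else p
                         for p in self.profiles]
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        data.setdefault("profiles", [])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def run_simulation(config: RunConfig, out_dir=None):
    """Generate the configured cohort, apply exclusions, and write
    trials.csv + manifest.json.  Returns (trials, manifest)."""
    profiles = config.resolved_profiles()
    trials, manifest = generate_cohort(profiles, config.seed)
    if config.apply_exclusions and len(trials):
        _, report = apply_exclusions(trials)
        trials = report.flagged
        manifest["exclusions"] = {
            "n_trials_excluded_rt": report.n_trials_excluded_rt,
            "participants_excluded": report.participants_excluded,
            "n_kept": report.n_kept,
        }
    manifest["config"] = config.to_dict()
    manifest["socddm_version"] = __version__
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trials(trials, out / "trials.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return trials, manifest


def recovery_study(seed: int = 0, n_participants: int = 17,
                   n_restarts: int = 1, n_boot: int = 200,
                   model_ids=(2, 3, 4), verbose=print) -> dict:
    """Generate one drift-bias and one starting-point-bias cohort and check
    that the pipeline recovers each mechanism.

    Returns a dict of named boolean checks (all True = pass): the
    psychometric shift of the drift-bias cohort is near its calibrated
    population value; model comparison prefers the advice-sensitive models
    appropriately; and the bootstrap flags isolate the generating mechanism.
    """
    from .models import FitOptions, build_model, compare_models, fit_all_models, \
        parameter_cis
    from .psychometrics import aggregate_points, fit_paired_gaussians
    from .cohort import calibrate_drift_bias, calibrate_k_v, expected_population_shift

    checks = {}
    k_v = calibrate_k_v()
    dv = calibrate_drift_bias()
    drift_prof = GroupProfile("drift_bias", n_participants, k_v, dv_advice=dv)
    z_prof = GroupProfile("z_bias", n_participants, k_v, z_advice=0.05)
    opts = FitOptions(n_restarts=n_restarts, seed=seed)

    for prof, mech in ((drift_prof, "drift"), (z_prof, "z")):
        trials, _ = generate_cohort([prof], seed + (0 if mech == "drift" else 1))
        kept, _ = apply_exclusions(trials)
        ptsL = aggregate_points(kept[kept.advice == "left"])
        ptsR = aggregate_points(kept[kept.advice == "right"])
        pf = fit_paired_gaussians(ptsL, ptsR, seed=seed, n_boot=200)
        target = expected_population_shift(prof)
        checks[f"{mech}:shift_recovered"] = bool(abs(pf.shift - target) < 0.1)
        verbose(f"[{mech}] psychometric shift {pf.shift:.3f} (population {target:.3f})")

        fits = fit_all_models(kept, model_ids=model_ids, options=opts)
        cmp_ = compare_models(fits)
        verbose(f"[{mech}] BIC: " + ", ".join(
            f"M{int(r.model)}={r.bic:.1f}" for r in cmp_["table"].itertuples()))
        if mech == "drift":
            if 2 in fits and 3 in fits:
                checks["drift:M3_beats_M2"] = bool(fits[3].bic < fits[2].bic)
        else:
            if 2 in fits and 3 in fits:
                checks["z:M2_beats_M3"] = bool(fits[2].bic < fits[3].bic)
        spec4 = build_model(4, np.unique(kept.disparity_norm))
        cis = parameter_cis(kept, spec4, n_boot=n_boot, seed=seed,
                            options=opts, point_fit=fits.get(4))
        dv_sig = bool(cis.loc[cis.quantity == "dv_mean", "significant"].iloc[0])
        z_sig = bool(cis.loc[cis.quantity == "z_displacement", "significant"].iloc[0])
        if mech == "drift":
            checks["drift:dv_flagged"] = dv_sig
            checks["drift:z_not_flagged"] = not z_sig
        else:
            checks["z:z_flagged"] = z_sig
            checks["z:dv_not_flagged"] = not dv_sig
        verbose(f"[{mech}] dv significant: {dv_sig}, z significant: {z_sig}")

    checks["all_passed"] = all(checks.values())
    return checks
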