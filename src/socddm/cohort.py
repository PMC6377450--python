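"""Synthetic behavioral cohorts for the social-advice cylinder task.

Each participant completes 210 trials in 10 blocks of 21: seven signed
disparities (three magnitudes, both signs, plus zero) crossed with advice
direction.  On unambiguous (nonzero-disparity) trials the advisor is
correct on exactly 2/3 of trials per level; at zero disparity advice is
balanced 50:50.  Choices and reaction times are drawn from the diffusion
model with group-specific social-influence mechanisms:

* a *drift bias*: advice adds ``dv_advice`` to the drift rate toward the
  advised direction (evidence-level integration of advice), and/or
* a *starting-point bias*: advice displaces the relative starting point by
  ``z_advice`` toward the advised direction (a prior-expectation shift).

The neurotypical adolescent preset carries a drift bias calibrated so that
the population psychometric shift equals 0.419 normalized disparity; the
younger-child and autistic presets carry starting-point biases.  The
sensory drift gain ``k_v`` is calibrated so accuracy at the largest
disparity is about 95%.  Both calibrations run on analytic choice
probabilities (bisection), so presets are reproducible from first
principles rather than stored constants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import __version__
from .config import DT_DEFAULT, S_DEFAULT
from .ddm import DiffusionParams, ParameterError, choice_probability, simulate_paths
from .psychometrics import _fit_paired_ml, normalize_disparities

__all__ = [
    "DISPARITY_RANGES", "GroupProfile", "build_design", "generate_participant",
    "generate_cohort", "apply_exclusions", "ExclusionReport",
    "expected_population_shift", "calibrate_k_v", "calibrate_drift_bias",
    "default_profiles", "preset_profile",
]

#: Disparity ranges (degrees) assigned by pre-measured stereo threshold.
DISPARITY_RANGES = {
    "high": (0.06, 0.04, 0.02),
    "mid": (0.03, 0.02, 0.01),
    "low": (0.015, 0.01, 0.005),
}

TRIALS_PER_LEVEL = 30
N_BLOCKS = 10
ADVICE_VALID_FRAC = 2.0 / 3.0

#: Study-scale cohort sizes per age band: (peer-advice NT, adult-advice NT,
#: autistic).
_GROUP_SIZES = {
    "NT_6_8": {"peer": 29, "adult": 20},
    "NT_9_11": {"peer": 15, "adult": 18},
    "NT_12_14": {"peer": 17, "adult": 26},
    "AUT_6_8": {"peer": 9},
    "AUT_9_11": {"peer": 11},
    "AUT_12_14": {"peer": 10},
}


@dataclass(frozen=True)
class GroupProfile:
    """Decision-parameter profile of one experimental group.

    ``k_v`` is the drift gain per unit normalized disparity; ``dv_advice``
    and ``z_advice`` encode the magnitude of the drift-rate and
    starting-point biases toward the advised direction (signs are applied
    per trial from the advice direction, left = positive).
    """
    label: str
    n_participants: int
    k_v: float
    dv_advice: float = 0.0
    z_advice: float = 0.0
    a: float = 0.14
    ter: float = 0.35
    eta: float = 0.08
    sz: float = 0.02
    st: float = 0.2
    s: float = S_DEFAULT
    threshold_range: str = "mid"
    anticonform_zero: float = 0.0  # optional opposite-direction z bias at 0 disparity

    def base_params(self) -> DiffusionParams:
        return DiffusionParams(v=0.0, a=self.a, z_rel=0.5, ter=self.ter,
                               eta=self.eta, sz=self.sz, st=self.st, s=self.s)

    def trial_params(self, disparity_norm: float, advice: str) -> DiffusionParams:
        s_adv = 1.0 if advice == "left" else -1.0
        z = 0.5 + s_adv * self.z_advice
        if disparity_norm == 0.0 and self.anticonform_zero:
            z = z - s_adv * self.anticonform_zero
        p = DiffusionParams(v=self.k_v * disparity_norm + s_adv * self.dv_advice,
                            a=self.a, z_rel=z, ter=self.ter, eta=self.eta,
                            sz=self.sz, st=self.st, s=self.s)
        try:
            return p.validate()
        except ParameterError as e:
            raise ParameterError(
                f"profile {self.label!r} invalid at disparity {disparity_norm}, "
                f"advice {advice}: {e}") from e


def _resolve_levels(threshold_range):
    if isinstance(threshold_range, str):
        try:
            mags = DISPARITY_RANGES[threshold_range]
        except KeyError:
            raise ValueError(f"unknown threshold range {threshold_range!r}")
        levels = sorted([m for m in mags] + [-m for m in mags] + [0.0])
    else:
        levels = sorted(float(x) for x in threshold_range)
        if len(levels) != 7:
            raise ValueError("need exactly 7 disparity levels")
        if 0.0 not in levels:
            raise ValueError("disparity list must include a zero level")
        pos = [x for x in levels if x > 0]
        neg = sorted(-x for x in levels if x < 0)
        if pos != neg:
            raise ValueError("disparity list must be sign-symmetric")
    return np.array(levels)


def build_design(threshold_range="mid", seed: int = 0,
                 advice_validity_per_level: bool = True) -> pd.DataFrame:
    """Ordered 210-trial skeleton: blocks, disparities and advice.

    Advice matches the stimulus direction on exactly 2/3 of trials at every
    nonzero disparity (set ``advice_validity_per_level=False`` to enforce
    2/3 only across all unambiguous trials jointly) and is balanced 50:50
    at zero disparity.  Trials are pseudorandomly interleaved within
    blocks, 3 per disparity level per block, reproducibly from ``seed``.
    """
    levels = _resolve_levels(threshold_range)
    rng = np.random.default_rng(seed)
    n_valid = int(round(TRIALS_PER_LEVEL * ADVICE_VALID_FRAC))

    per_level_advice = {}
    if advice_validity_per_level:
        for d in levels:
            if d == 0.0:
                adv = np.array(["left"] * (TRIALS_PER_LEVEL // 2)
                               + ["right"] * (TRIALS_PER_LEVEL // 2))
            else:
                stim = "left" if d > 0 else "right"
                other = "right" if d > 0 else "left"
                adv = np.array([stim] * n_valid + [other] * (TRIALS_PER_LEVEL - n_valid))
            rng.shuffle(adv)
            per_level_advice[d] = adv
    else:
        nz = [d for d in levels if d != 0.0]
        valid = np.zeros(TRIALS_PER_LEVEL * len(nz), dtype=bool)
        valid[:int(round(ADVICE_VALID_FRAC * valid.size))] = True
        rng.shuffle(valid)
        for i, d in enumerate(nz):
            stim = "left" if d > 0 else "right"
            other = "right" if d > 0 else "left"
            vv = valid[i * TRIALS_PER_LEVEL:(i + 1) * TRIALS_PER_LEVEL]
            per_level_advice[d] = np.where(vv, stim, other)
        adv = np.array(["left"] * (TRIALS_PER_LEVEL // 2)
                       + ["right"] * (TRIALS_PER_LEVEL // 2))
        rng.shuffle(adv)
        per_level_advice[0.0] = adv

    rows = []
    per_block = TRIALS_PER_LEVEL // N_BLOCKS
    for b in range(N_BLOCKS):
        block_rows = []
        for d in levels:
            for j in range(per_block):
                adv = per_level_advice[d][b * per_block + j]
                block_rows.append((b + 1, d, adv))
        order = rng.permutation(len(block_rows))
        rows.extend(block_rows[i] for i in order)

    df = pd.DataFrame(rows, columns=["block", "disparity_deg", "advice"])
    df["disparity_norm"] = normalize_disparities(df["disparity_deg"].to_numpy())
    stim_dir = np.where(df.disparity_deg > 0, "left",
                        np.where(df.disparity_deg < 0, "right", ""))
    df["advice_correct"] = pd.array(
        np.where(stim_dir == "", pd.NA, df.advice == stim_dir), dtype="boolean")
    return df


def generate_participant(profile: GroupProfile, participant_seed: int,
                         participant_id: str | None = None,
                         dt: float = DT_DEFAULT) -> pd.DataFrame:
    """Simulate one participant's 210 trials under the profile's mechanism.

    Per trial: drift ``v = k_v*disparity_norm + sign(advice)*dv_advice`` and
    relative start ``z = 0.5 + sign(advice)*z_advice`` (left positive), with
    the profile's across-trial variability; outcomes via the Euler path
    simulator.  Non-absorbed paths (cap 30 s) keep ``response`` empty and
    are flagged non-terminated.
    """
    ss = np.random.SeedSequence(participant_seed)
    rng = np.random.default_rng(ss)
    design_seed = int(ss.generate_state(3)[2] % (2 ** 31 - 1))
    design = build_design(profile.threshold_range, seed=design_seed)

    n = len(design)
    s_adv = np.where(design.advice.to_numpy() == "left", 1.0, -1.0)
    d_norm = design.disparity_norm.to_numpy()
    v_mean = profile.k_v * d_norm + s_adv * profile.dv_advice
    z_rel = 0.5 + s_adv * profile.z_advice
    if profile.anticonform_zero:
        z_rel = np.where(d_norm == 0.0, z_rel - s_adv * profile.anticonform_zero, z_rel)
    # validate the distinct per-trial parameter cells up front
    for d in np.unique(d_norm):
        for adv in ("left", "right"):
            profile.trial_params(float(d), adv)

    vs = rng.normal(v_mean, profile.eta) if profile.eta > 0 else v_mean
    z_abs = z_rel * profile.a
    if profile.sz > 0:
        z_abs = rng.uniform(z_abs - 0.5 * profile.sz, z_abs + 0.5 * profile.sz)
    ters = rng.uniform(profile.ter - 0.5 * profile.st, profile.ter + 0.5 * profile.st, n) \
        if profile.st > 0 else np.full(n, profile.ter)
    path_seed = int(ss.generate_state(2)[1] % (2 ** 31 - 1))
    code, rt = simulate_paths(vs, z_abs, ters, profile.a, profile.s,
                              seed=path_seed, dt=dt)

    out = design.copy()
    out.insert(0, "participant", participant_id or f"{profile.label}_p0")
    out.insert(1, "group", profile.label)
    out["response"] = pd.Categorical.from_codes(
        np.select([code == 1, code == 0], [0, 1], default=-1),
        categories=["left", "right"])
    out["rt_s"] = rt
    out["terminated"] = code >= 0
    out["conformed"] = pd.array(
        np.where(code < 0, pd.NA, out.response == out.advice), dtype="boolean")
    out["excluded"] = False
    out["exclude_reason"] = ""
    return out


def generate_cohort(profiles, master_seed: int,
                    dt: float = DT_DEFAULT) -> tuple[pd.DataFrame, dict]:
    """Generate a full multi-group dataset plus a reproducibility manifest.

    Deterministic per ``master_seed``: participant seeds are spawned from a
    single SeedSequence, so regenerating from the manifest reproduces the
    dataset byte-identically.
    """
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate profile labels")
    frames = []
    manifest = {"socddm_version": __version__, "master_seed": int(master_seed),
                "dt": dt, "profiles": [], "participants": []}
    ss = np.random.SeedSequence(master_seed)
    for profile in profiles:
        child = ss.spawn(1)[0]
        pseeds = child.generate_state(profile.n_participants) % (2 ** 31 - 1)
        manifest["profiles"].append(dataclasses.asdict(profile))
        for i, pseed in enumerate(pseeds):
            pid = f"{profile.label}_p{i + 1:02d}"
            manifest["participants"].append({"id": pid, "seed": int(pseed)})
            frames.append(generate_participant(profile, int(pseed), pid, dt=dt))
    if not frames:
        return pd.DataFrame(), manifest
    return pd.concat(frames, ignore_index=True), manifest


@dataclass
class ExclusionReport:
    n_input: int
    n_trials_excluded_rt: int
    participants_excluded: dict = field(default_factory=dict)
    n_kept: int = 0
    flagged: pd.DataFrame | None = None


def apply_exclusions(trials: pd.DataFrame, rt_cap: float = 8.0,
                     accuracy_floor: float = 0.85,
                     bias_cap: float = 0.80) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the trial- and participant-level exclusion rules.

    * trials with rt strictly greater than ``rt_cap`` (8 s) are excluded;
    * participants below ``accuracy_floor`` (exactly 85% passes) correct at
      the largest absolute disparity are excluded entirely;
    * participants with strictly more than ``bias_cap`` (80%) of responses
      toward either side at zero disparity are excluded entirely.

    Participant statistics are computed on rt-surviving, absorbed trials, so
    the operation is idempotent and independent of rule ordering.  Returns
    the kept trials and a report whose ``flagged`` table preserves every
    input row with its exclusion flag and reason.
    """
    if len(trials) == 0:
        return trials.copy(), ExclusionReport(0, 0, {}, 0, trials.copy())
    t = trials.copy()
    rt_bad = t["rt_s"].to_numpy() > rt_cap
    if "terminated" in t.columns:
        rt_bad = rt_bad | ~t["terminated"].to_numpy()
    reasons = np.where(rt_bad, "rt_gt_8s", "")

    base = t.loc[~rt_bad]
    part_reason = {}
    for pid, sub in base.groupby("participant", observed=True):
        nz = sub[sub["disparity_deg"] != 0]
        d_abs = nz["disparity_deg"].abs()
        top = nz[d_abs == d_abs.max()] if len(nz) else nz
        stim = np.where(top["disparity_deg"] > 0, "left", "right")
        acc = float((top["response"].to_numpy() == stim).mean()) if len(top) else 1.0
        zero = sub[sub["disparity_deg"] == 0]
        if len(zero):
            p_left = float((zero["response"] == "left").mean())
            bias = max(p_left, 1.0 - p_left)
        else:
            bias = 0.0
        if acc < accuracy_floor:
            part_reason[pid] = "participant_accuracy_lt_85"
        elif bias > bias_cap:
            part_reason[pid] = "participant_bias_gt_80"
    part_bad = t["participant"].map(part_reason).notna().to_numpy() if part_reason \
        else np.zeros(len(t), dtype=bool)
    reasons = np.where((reasons == "") & part_bad,
                       t["participant"].map(part_reason).fillna("").to_numpy(), reasons)
    excluded = reasons != ""
    t["excluded"] = excluded
    t["exclude_reason"] = reasons
    kept = t.loc[~excluded].copy()
    report = ExclusionReport(
        n_input=len(t),
        n_trials_excluded_rt=int(rt_bad.sum()),
        participants_excluded=part_reason,
        n_kept=len(kept),
        flagged=t,
    )
    return kept, report


# ---------------------------------------------------------------------------
# analytic calibration of the presets
# ---------------------------------------------------------------------------

def _design_weights(levels):
    """Trial counts per (disparity, advice) cell implied by the design."""
    w = {}
    n_valid = int(round(TRIALS_PER_LEVEL * ADVICE_VALID_FRAC))
    for d in levels:
        if d == 0:
            w[(d, "left")] = TRIALS_PER_LEVEL // 2
            w[(d, "right")] = TRIALS_PER_LEVEL // 2
        elif d > 0:
            w[(d, "left")] = n_valid
            w[(d, "right")] = TRIALS_PER_LEVEL - n_valid
        else:
            w[(d, "right")] = n_valid
            w[(d, "left")] = TRIALS_PER_LEVEL - n_valid
    return w


def expected_population_shift(profile: GroupProfile) -> float:
    """Population psychometric shift implied by a profile, computed from
    analytic choice probabilities and the design's cell counts (no
    simulation noise)."""
    levels = normalize_disparities(_resolve_levels(profile.threshold_range))
    weights = _design_weights(levels)
    dL, kL, nL, dR, kR, nR = [], [], [], [], [], []
    for d in levels:
        for adv, (dd, kk, nn) in (("left", (dL, kL, nL)), ("right", (dR, kR, nR))):
            p = choice_probability(profile.trial_params(float(d), adv), "left")
            n_cell = weights[(float(d), adv)]
            dd.append(float(d))
            kk.append(p * n_cell)
            nn.append(n_cell)
    muL, muR, _, _, _ = _fit_paired_ml(np.array(dL), np.array(kL), np.array(nL),
                                       np.array(dR), np.array(kR), np.array(nR))
    return float(muR - muL)


@lru_cache(maxsize=None)
def calibrate_k_v(a: float = 0.14, ter: float = 0.35, eta: float = 0.08,
                  sz: float = 0.02, st: float = 0.2, s: float = S_DEFAULT,
                  target_accuracy: float = 0.95) -> float:
    """Drift gain such that accuracy at the largest disparity hits the
    target (root-found on the analytic choice probability)."""
    def acc(k_v):
        p = DiffusionParams(v=k_v, a=a, z_rel=0.5, ter=ter, eta=eta, sz=sz, st=st, s=s)
        return choice_probability(p, "left") - target_accuracy
    return float(brentq(acc, 0.01, 3.0, xtol=1e-6))


@lru_cache(maxsize=None)
def calibrate_drift_bias(target_shift: float = 0.419, k_v: float | None = None,
                         a: float = 0.14, ter: float = 0.35, eta: float = 0.08,
                         sz: float = 0.02, st: float = 0.2,
                         s: float = S_DEFAULT) -> float:
    """Advice drift bias such that the population psychometric shift equals
    the target (bisection on the analytic shift)."""
    if k_v is None:
        k_v = calibrate_k_v(a, ter, eta, sz, st, s)

    def shift_of(dv):
        prof = GroupProfile(label="_cal", n_participants=1, k_v=k_v,
                            dv_advice=dv, a=a, ter=ter, eta=eta, sz=sz, st=st, s=s)
        return expected_population_shift(prof) - target_shift
    return float(brentq(shift_of, 0.0, k_v, xtol=1e-6))


#: Starting-point bias magnitudes for the presets that carry one.  The
#: younger neurotypical groups show a prior-expectation (starting point)
#: effect that grows with age but essentially no psychometric shift; the
#: autistic groups show a persistent starting-point bias at all ages.
_Z_ADVICE_PRESETS = {
    "NT_6_8": 0.02,
    "NT_9_11": 0.03,
    "NT_12_14": 0.0,
    "AUT_6_8": 0.06,
    "AUT_9_11": 0.06,
    "AUT_12_14": 0.06,
}


def preset_profile(label: str, advisor: str = "adult",
                   n_participants: int | None = None) -> GroupProfile:
    """One of the six study-group presets (NT/AUT x three age bands)."""
    if label not in _GROUP_SIZES:
        raise ValueError(f"unknown preset {label!r}; choose from {sorted(_GROUP_SIZES)}")
    sizes = _GROUP_SIZES[label]
    if advisor not in sizes:
        raise ValueError(f"group {label} was not run with advisor {advisor!r}")
    k_v = calibrate_k_v()
    dv = calibrate_drift_bias() if label == "NT_12_14" else 0.0
    return GroupProfile(label=label,
                        n_participants=n_participants or sizes[advisor],
                        k_v=k_v, dv_advice=dv,
                        z_advice=_Z_ADVICE_PRESETS[label])


def default_profiles(advisor: str = "adult"):
    """The full default cohort: the three neurotypical age bands for the
    chosen advisor plus, for peer advice, the three autistic groups."""
    labels = ["NT_6_8", "NT_9_11", "NT_12_14"]
    if advisor == "peer":
        labels += ["AUT_6_8", "AUT_9_11", "AUT_12_14"]
    return [preset_profile(lb, advisor) for lb in labels]
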