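"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of its configuration (seed included), so
identical configs give identical outputs and every downstream recovery test
is self-contained.  The generators emulate, at configurable size:

* a small treated/control training set (default 5 treated vs 18 control
  samples on a 22,283-probe U133A-like array) whose treatment effect lives
  on a planted set of probes, each shifted by ``effect_sd`` within-class
  standard deviations along a random sign pattern;
* subtype-labelled tumor cohorts whose latent pathway activation varies by
  intrinsic subtype.  A sample's "treatment-likeness" is tau = 0.5 -
  activation: strongly pathway-driven (activated) tumors look like
  *untreated* cells and are the sensitive ones, mirroring the biology that
  the drug shuts the pathway down;
* 10-dose viability plates on the screen's dose ladder (0 and 0.1 pM to
  1 nM) with multiplicative lognormal noise;
* xenograft caliper time courses with per-animal lognormal growth-rate
  heterogeneity, where each drug arm's expected endpoint volume gain is
  (1 - tgi_true) times the control-trajectory gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expr_io import ExpressionMatrix, Scale
from .pharmacodynamics import DoseResponsePlate
from .xenograft import stratified_randomize

__all__ = [
    "DOSES_MOLAR",
    "SimulationConfig",
    "simulate_training_set",
    "simulate_cohort",
    "simulate_dose_response",
    "simulate_sensitivity_ec50_panel",
    "simulate_xenograft_trial",
]

# The screen's dose ladder: vehicle plus 0.1 pM .. 1 nM.
DOSES_MOLAR = np.array([0.0, 0.1e-12, 0.3e-12, 1e-12, 3e-12,
                        10e-12, 30e-12, 100e-12, 300e-12, 1e-9])

# Subtype mean activations chosen so that, with activation_sd = 0.35, the
# probability of a sample falling on the sensitive side of the decision
# midpoint is roughly the frequency reported for that subtype in large
# breast-cancer cohorts (basal-like highest, luminal A lowest).
_DEFAULT_ACTIVATION = {
    "basal-like": 0.55,
    "HER2-overexpressing": 0.16,
    "luminal B": 0.07,
    "normal-like": -0.12,
    "luminal A": -0.32,
}

_DEFAULT_COHORT_SIZES = {
    "basal-like": 253,
    "HER2-overexpressing": 178,
    "luminal A": 435,
    "luminal B": 285,
    "normal-like": 250,
}

_DEFAULT_TGI = {"rapamycin": 0.94, "CCI-779": 0.94, "doxorubicin": 0.36}


@dataclass
class SimulationConfig:
    """Study-scale defaults for all generators.

    effect_sd is the planted per-probe shift in units of the within-class
    log2 SD (noise_sd); activation is on the treatment-likeness scale where
    0 is an untreated training sample and 1 a treated one.
    """

    seed: int = 0
    structure_seed: int | None = None  # probe-space "biology"; defaults to seed
    n_probes: int = 22283
    n_planted: int = 200
    effect_sd: float = 2.0
    n_treated: int = 5
    n_control: int = 18
    noise_sd: float = 0.5
    subtype_activation: dict = field(
        default_factory=lambda: dict(_DEFAULT_ACTIVATION))
    activation_sd: float = 0.35
    cohort_sizes: dict = field(
        default_factory=lambda: dict(_DEFAULT_COHORT_SIZES))
    ec50_range: tuple = (1e-14, 1e-7)
    tgi_true: dict = field(default_factory=lambda: dict(_DEFAULT_TGI))
    viability_cv: float = 0.10
    growth_rate: float = np.log(2.0) / 7.0   # control doubling time ~1 week
    growth_rate_cv: float = 0.10
    measurement_cv: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.n_planted <= self.n_probes:
            raise ValueError("need 0 < n_planted <= n_probes")
        for name in ("n_treated", "n_control", "n_probes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if any(not 0.0 <= v <= 1.0 for v in self.tgi_true.values()):
            raise ValueError("tgi_true fractions must lie in [0, 1]")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _gene_index(n_probes: int) -> np.ndarray:
    # deterministic many-to-one pattern, ~1.7 probes per gene (U133A-like)
    return np.arange(n_probes) * 10 // 17


def _structure(cfg: SimulationConfig):
    """Probe-space structure shared by the training and cohort generators.

    Derived from ``structure_seed`` (default: ``seed``) so that independent
    sampling replicates — new cohorts, new noise — can share one "biology".
    The treatment effect is planted gene-wise: whole genes respond, so all
    of a responding gene's probes shift with a common sign, as on real
    arrays where signatures pick up several probes of the same gene.
    """
    rng = np.random.default_rng(
        [cfg.seed if cfg.structure_seed is None else cfg.structure_seed, 0])
    baseline = rng.uniform(6.0, 12.0, cfg.n_probes)
    gi = _gene_index(cfg.n_probes)
    genes = np.unique(gi)
    order = rng.permutation(len(genes))
    planted_list = []
    gene_sign = {}
    for g in genes[order]:
        if len(planted_list) >= cfg.n_planted:
            break
        members = np.flatnonzero(gi == g)
        take = members[:cfg.n_planted - len(planted_list)]
        planted_list.extend(take)
        gene_sign[g] = rng.choice([-1.0, 1.0])
    planted = np.sort(np.asarray(planted_list, dtype=int))
    delta = np.zeros(cfg.n_probes)
    delta[planted] = cfg.effect_sd * cfg.noise_sd * np.array(
        [gene_sign[gi[i]] for i in planted])
    probe_ids = np.array([f"probe_{i:05d}" for i in range(cfg.n_probes)])
    return probe_ids, baseline, planted, delta


def probe_gene_map(cfg: SimulationConfig) -> pd.Series:
    """Deterministic many-to-one probe -> gene map (~1.7 probes per gene)."""
    probe_ids = np.array([f"probe_{i:05d}" for i in range(cfg.n_probes)])
    genes = np.array([f"GENE{g:05d}" for g in _gene_index(cfg.n_probes)])
    return pd.Series(genes, index=probe_ids, name="gene_symbol")


def _expression(cfg, baseline, delta, tau, rng) -> np.ndarray:
    """Linear-scale intensities 2^(baseline + tau*delta + noise)."""
    log2 = (baseline[:, None] + np.outer(delta, tau)
            + rng.normal(0.0, cfg.noise_sd, (cfg.n_probes, len(tau))))
    return np.exp2(log2)


def simulate_training_set(cfg: SimulationConfig):
    """Treated/control training set with a planted low-dimensional effect.

    Returns (linear-scale ExpressionMatrix, annotation DataFrame, truth
    dict).  Truth carries the planted probe ids, the per-probe log2 shift
    and each sample's treatment-likeness tau (1 treated, 0 control).
    """
    probe_ids, baseline, planted, delta = _structure(cfg)
    rng = _rng(cfg, 1)
    sample_ids = ([f"treated_{i + 1:02d}" for i in range(cfg.n_treated)]
                  + [f"control_{i + 1:02d}" for i in range(cfg.n_control)])
    tau = np.r_[np.ones(cfg.n_treated), np.zeros(cfg.n_control)]
    values = _expression(cfg, baseline, delta, tau, rng)
    em = ExpressionMatrix(pd.DataFrame(values, index=probe_ids,
                                       columns=sample_ids), scale=Scale.linear)
    ann = pd.DataFrame({
        "sample_id": sample_ids,
        "class_label": ["treated"] * cfg.n_treated + ["control"] * cfg.n_control,
        "subtype": "none",
        "study_id": "sim_train",
    })
    truth = {"planted_probes": probe_ids[planted], "delta": delta,
             "tau": pd.Series(tau, index=sample_ids)}
    return em, ann, truth


def simulate_cohort(cfg: SimulationConfig):
    """Subtype-labelled cohort with subtype-dependent pathway activation.

    Per sample, activation ~ Normal(subtype_activation[subtype],
    activation_sd) and treatment-likeness tau = 0.5 - activation, so highly
    activated subtypes sit on the untreated-like (sensitive) side of the
    decision midpoint.  Returns (linear-scale ExpressionMatrix, annotation
    DataFrame, activation Series).
    """
    probe_ids, baseline, planted, delta = _structure(cfg)
    rng = _rng(cfg, 2)
    ids, subtypes, acts = [], [], []
    counter = 0
    for subtype, n in cfg.cohort_sizes.items():
        if n <= 0:
            continue
        if subtype not in cfg.subtype_activation:
            continue
        a = rng.normal(cfg.subtype_activation[subtype], cfg.activation_sd, n)
        for ai in a:
            ids.append(f"tumor_{counter:04d}")
            subtypes.append(subtype)
            acts.append(ai)
            counter += 1
    activation = pd.Series(acts, index=ids, name="activation")
    tau = 0.5 - activation.to_numpy()
    values = _expression(cfg, baseline, delta, tau, rng)
    em = ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=ids),
                          scale=Scale.linear)
    ann = pd.DataFrame({"sample_id": ids, "class_label": "unknown",
                        "subtype": subtypes, "study_id": "sim_cohort"})
    return em, ann, activation


def simulate_dose_response(cfg: SimulationConfig, true_ec50: dict,
                           n_replicates: int = 3, top: float = 1000.0,
                           bottom_frac: float = 0.05) -> list:
    """Viability plates from the hill-1 sigmoid at the screen's 10 doses.

    ``true_ec50`` maps cell line -> EC50 (molar, within cfg.ec50_range).
    Noise is multiplicative lognormal with CV ``cfg.viability_cv``.
    """
    lo, hi = cfg.ec50_range
    for line, ec50 in true_ec50.items():
        if not lo <= ec50 <= hi:
            raise ValueError(f"true EC50 for {line!r} outside ec50_range")
    rng = _rng(cfg, 3)
    sigma = np.sqrt(np.log1p(cfg.viability_cv**2))
    bottom = bottom_frac * top
    plates = []
    for line, ec50 in true_ec50.items():
        mean = bottom + (top - bottom) / (1.0 + DOSES_MOLAR / ec50)
        noise = np.exp(rng.normal(0.0, sigma, (len(DOSES_MOLAR), n_replicates)))
        plates.append(DoseResponsePlate(
            cell_line=line, doses=DOSES_MOLAR,
            viability=list(mean[:, None] * noise)))
    return plates


def simulate_sensitivity_ec50_panel(cfg: SimulationConfig, n_lines: int = 18,
                                    target_r: float = -0.3,
                                    decades_per_unit: float = 1.0):
    """Cell-line panel where true sensitivity drives EC50 with tuned noise.

    Sensitivity is uniform on [0, 1]; log10 EC50 decreases by
    ``decades_per_unit`` per unit sensitivity, plus Gaussian noise sized so
    the population correlation is ``target_r``.  Returns (sensitivity
    Series, true_ec50 dict) for feeding simulate_dose_response or the
    regression directly.
    """
    if not -1.0 < target_r < 0.0:
        raise ValueError("target_r must be in (-1, 0)")
    rng = _rng(cfg, 5)
    lines = [f"line_{i + 1:02d}" for i in range(n_lines)]
    sens = rng.uniform(0.0, 1.0, n_lines)
    sd_s = np.sqrt(1.0 / 12.0)
    sd_noise = decades_per_unit * sd_s * np.sqrt(1.0 / target_r**2 - 1.0)
    center = np.log10(np.sqrt(cfg.ec50_range[0] * cfg.ec50_range[1]))
    log_ec50 = (center + decades_per_unit * (0.5 - sens)
                + rng.normal(0.0, sd_noise, n_lines))
    lo, hi = np.log10(cfg.ec50_range)
    log_ec50 = np.clip(log_ec50, lo, hi)
    return (pd.Series(sens, index=lines, name="sensitivity"),
            dict(zip(lines, 10.0 ** log_ec50)))


def _measurement_days(last_day: int) -> list:
    days, d, step = [0], 0, 3
    while d + step <= last_day:
        d += step
        days.append(d)
        step = 7 - step  # alternate 3- and 4-day gaps: twice-weekly calipers
    return days


def simulate_xenograft_trial(cfg: SimulationConfig, model_id: str = "model_1",
                             arms=("control", "rapamycin"),
                             n_per_group: int = 8, days: int = 42,
                             stream: int = 4) -> pd.DataFrame:
    """Caliper measurement table for one xenograft model.

    Baseline volumes are uniform on [50, 100] mm^3 (the enrollment window);
    animals are stratified-randomized to arms by baseline volume.  Each
    animal grows exponentially with a lognormal individual rate; in a drug
    arm the rate is deflected so the animal's expected endpoint volume gain
    is (1 - tgi_true[arm]) times its control-trajectory gain, which makes
    endpoint TGI estimates converge to the programmed suppression.  Volumes
    acquire lognormal measurement noise and are reported as (l, w) caliper
    pairs with aspect ratio w/l uniform on [0.5, 1].
    """
    arms = list(arms)
    unknown = [a for a in arms if a != "control" and a not in cfg.tgi_true]
    if unknown:
        raise ValueError(f"no tgi_true entry for arm(s) {unknown}")
    rng = _rng(cfg, stream)
    n = n_per_group * len(arms)
    animal_ids = [f"{model_id}_m{i + 1:02d}" for i in range(n)]
    v0 = rng.uniform(50.0, 100.0, n)
    assign = stratified_randomize(
        pd.Series(v0, index=animal_ids), arms,
        seed=int(rng.integers(2**31)),
        group_sizes={a: n_per_group for a in arms})
    g = cfg.growth_rate * np.exp(
        rng.normal(0.0, cfg.growth_rate_cv, n)
        - cfg.growth_rate_cv**2 / 2.0)
    day_grid = _measurement_days(days)
    t_end = day_grid[-1]
    rows = []
    for i, animal in enumerate(animal_ids):
        arm = assign[animal]
        tgi = 0.0 if arm == "control" else cfg.tgi_true[arm]
        # rate such that V0*(e^{g_eff*T} - 1) = (1-tgi)*V0*(e^{g*T} - 1)
        gain = np.expm1(g[i] * t_end)
        g_eff = np.log1p((1.0 - tgi) * gain) / t_end
        for day in day_grid:
            v = v0[i] * np.exp(g_eff * day)
            if day > 0:
                v *= np.exp(rng.normal(0.0, cfg.measurement_cv))
            aspect = rng.uniform(0.5, 1.0)
            l = (2.0 * v / aspect**2) ** (1.0 / 3.0)
            rows.append({"animal_id": animal, "model_id": model_id,
                         "group": arm, "day": day,
                         "l_mm": l, "w_mm": aspect * l})
    return pd.DataFrame(rows)
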