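"""Synthetic microcosm generator.

Simulates discrete-time community dynamics with the same statistical
structure the downstream regression assumes: per-capita growth-rate
responses that are linear (Lotka-Volterra) or log-linear (Ricker) in
species densities, optionally with quadratic (intraspecific HOI) and
cross-product (interspecific HOI) terms, multiplicative lognormal
process noise, and an observation layer that mimics counting organisms
in small subsamples.

The update rule inverts the response convention used by the growth-rate
module: with per-day response ``r_i(N) = lambda_i - sum_j alpha_ij N_j - ...``
(LV) or ``lambda_i * exp(-sum_j alpha_ij N_j - ...)`` (Ricker), densities
advance as ``N_i(t+dt) = N_i(t) * max(r_i, 0) * dt * eps`` where ``eps``
is lognormal with median 1. A population is therefore stationary when
``r_i * dt = 1``, i.e. at response ``r_i = 1/dt`` per day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import TimeSeriesTable
from .species import Species, Treatment, TREATMENT_ORDER

FAMILIES = ("LV", "Ricker")
HOI_STRUCTURES = ("none", "intra", "inter", "full")


@dataclass
class SimParams:
    """Dynamics parameters for one community.

    Densities are in individuals/mL and time in days throughout.

    Attributes
    ----------
    species : list[Species]
        Community members in canonical order.
    lambda_ : dict[str, float]
        Intrinsic per-day growth-rate response lambda_i; a population at
        vanishing density grows when ``lambda_i * dt > 1``.
    alpha : dict[(str, str), float]
        Pairwise coefficients alpha_ij (effect of N_j on the response of
        i), per (individuals/mL); positive = suppression.
    beta_intra : dict[(str, str), float]
        Intraspecific-HOI coefficients beta_ijj on N_j^2, per (ind/mL)^2.
    beta_inter : dict[(str, str, str), float]
        Interspecific-HOI coefficients beta_ijk on N_j*N_k for unordered
        pairs j<k (canonical order), per (ind/mL)^2.
    family : {"LV", "Ricker"}
    hoi_structure : {"none", "intra", "inter", "full"}
    carrying_capacity : dict[str, float]
        Monoculture equilibrium K_i; initial consumer densities are
        ``init_fraction * K_i``.
    predator_schedule : list[(float, float, float)]
        (day, individuals added, culture volume mL) introduction events
        for the predator; the default mirrors two batches of ten
        individuals on days 4 and 8 into a 100 mL culture.
    process_noise_sd : float
        sigma of the lognormal step multiplier (median 1).
    extinction_threshold : float
        Densities below this are set to 0 and stay 0 (default: one
        individual per 100 mL culture).
    """

    species: list[Species]
    lambda_: dict[str, float]
    alpha: dict[tuple[str, str], float] = field(default_factory=dict)
    beta_intra: dict[tuple[str, str], float] = field(default_factory=dict)
    beta_inter: dict[tuple[str, str, str], float] = field(default_factory=dict)
    family: str = "LV"
    hoi_structure: str = "none"
    carrying_capacity: dict[str, float] = field(default_factory=dict)
    init_fraction: float = 0.10
    dt: float = 2.0
    horizon: float = 53.0
    process_noise_sd: float = 0.05
    extinction_threshold: float = 0.01
    predator_schedule: list[tuple[float, float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.species = [Species(sp) for sp in self.species]
        codes = [sp.value for sp in self.species]
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.hoi_structure not in HOI_STRUCTURES:
            raise ValueError(f"hoi_structure must be one of {HOI_STRUCTURES}")
        if not 0.0 < self.init_fraction <= 1.0:
            raise ValueError("init_fraction must be in (0, 1]")
        if self.dt <= 0 or self.horizon < self.dt:
            raise ValueError("require dt > 0 and horizon >= dt")
        if self.process_noise_sd < 0:
            raise ValueError("process_noise_sd must be >= 0")
        missing = [c for c in codes if c not in self.lambda_]
        if missing:
            raise ValueError(f"lambda_ missing for species {missing}")
        for key in self.alpha:
            if key[0] not in codes or key[1] not in codes:
                raise ValueError(f"alpha key {key} outside community {codes}")

    @property
    def codes(self) -> list[str]:
        return [sp.value for sp in self.species]

    def sampling_days(self) -> np.ndarray:
        """Days {0, dt, 2*dt, ...} up to the largest multiple <= horizon."""
        n_steps = int(np.floor(self.horizon / self.dt + 1e-9))
        return np.arange(n_steps + 1) * self.dt

    def responses(self, densities: np.ndarray) -> np.ndarray:
        """Per-day growth-rate response of every species at state ``densities``."""
        codes = self.codes
        n = len(codes)
        lam = np.array([self.lambda_[c] for c in codes])
        load = np.zeros(n)
        for i, ci in enumerate(codes):
            acc = 0.0
            for j, cj in enumerate(codes):
                acc += self.alpha.get((ci, cj), 0.0) * densities[j]
            if self.hoi_structure in ("intra", "full"):
                for j, cj in enumerate(codes):
                    acc += self.beta_intra.get((ci, cj), 0.0) * densities[j] ** 2
            if self.hoi_structure in ("inter", "full"):
                for j in range(n):
                    for k in range(j + 1, n):
                        acc += (
                            self.beta_inter.get((ci, codes[j], codes[k]), 0.0)
                            * densities[j] * densities[k]
                        )
            load[i] = acc
        if self.family == "LV":
            return lam - load
        return lam * np.exp(-load)

    def initial_densities(self) -> np.ndarray:
        init = np.empty(len(self.species))
        for i, sp in enumerate(self.species):
            if sp.is_predator:
                init[i] = 0.0  # predators enter via the schedule
            else:
                init[i] = self.init_fraction * self.carrying_capacity[sp.value]
        return init

    def to_dict(self) -> dict:
        d = asdict(self)
        d["species"] = [sp.value for sp in self.species]
        d["alpha"] = {f"{i},{j}": v for (i, j), v in self.alpha.items()}
        d["beta_intra"] = {f"{i},{j}": v for (i, j), v in self.beta_intra.items()}
        d["beta_inter"] = {f"{i},{j},{k}": v for (i, j, k), v in self.beta_inter.items()}
        d["predator_schedule"] = [list(ev) for ev in self.predator_schedule]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        d["alpha"] = {tuple(k.split(",")): v for k, v in d.get("alpha", {}).items()}
        d["beta_intra"] = {tuple(k.split(",")): v for k, v in d.get("beta_intra", {}).items()}
        d["beta_inter"] = {tuple(k.split(",")): v for k, v in d.get("beta_inter", {}).items()}
        d["predator_schedule"] = [tuple(ev) for ev in d.get("predator_schedule", [])]
        return cls(**d)


@dataclass
class ObservationParams:
    """Subsample-counting observation model.

    Density is measured as the mean of ``n_subsamples`` independent
    subsample counts, each count drawn Poisson with mean
    ``density * subsample_volume_ml`` and converted back to a density.
    """

    subsample_volume_ml: float = 0.25
    n_subsamples: int = 3
    counting_noise: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subsample_volume_ml <= 0:
            raise ValueError("subsample_volume_ml must be > 0")
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")
        if self.counting_noise not in ("poisson", "none"):
            raise ValueError("counting_noise must be 'poisson' or 'none'")

    def to_dict(self) -> dict:
        return asdict(self)


class SimulationError(RuntimeError):
    pass


def generate_design(replicates: int) -> list[tuple[str, Treatment, int]]:
    """All treatments crossed with replicate indices, deterministic ids."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    design = []
    for code in TREATMENT_ORDER:
        for rep in range(1, replicates + 1):
            design.append((f"{code}_r{rep}", Treatment(code), rep))
    return design


def simulate_community(
    params: SimParams,
    *,
    microcosm_id: str | None = None,
    replicate: int = 1,
) -> TimeSeriesTable:
    """Iterate the community map and return latent true densities.

    One microcosm on the sampling grid ``params.sampling_days()``.
    """
    days = params.sampling_days()
    codes = params.codes
    treatment_code = "".join(codes)
    if microcosm_id is None:
        microcosm_id = f"{treatment_code}_r{replicate}"

    rng = np.random.default_rng(params.seed)
    n = len(codes)
    dens = params.initial_densities()
    pd_idx = codes.index("Pd") if "Pd" in codes else None
    traj = np.empty((len(days), n))

    def apply_schedule(day: float, state: np.ndarray) -> None:
        if pd_idx is None:
            return
        for ev_day, individuals, volume in params.predator_schedule:
            if np.isclose(ev_day, day):
                state[pd_idx] += individuals / volume

    apply_schedule(days[0], dens)
    traj[0] = dens
    for step, day in enumerate(days[1:], start=1):
        r = params.responses(dens)
        r = np.maximum(r, 0.0)  # the discrete LV map is unbounded below
        growth = r * params.dt
        if params.process_noise_sd > 0:
            growth = growth * rng.lognormal(0.0, params.process_noise_sd, size=n)
        dens = dens * growth
        if not np.all(np.isfinite(dens)):
            bad = codes[int(np.argmax(~np.isfinite(dens)))]
            raise SimulationError(
                f"non-finite density for species {bad} at day {day} "
                f"in microcosm {microcosm_id}"
            )
        dens[dens < params.extinction_threshold] = 0.0
        apply_schedule(day, dens)
        traj[step] = dens

    records = pd.DataFrame({
        "microcosm_id": np.repeat(microcosm_id, len(days) * n),
        "treatment": treatment_code,
        "replicate": replicate,
        "day": np.repeat(days, n),
        "species": np.tile(codes, len(days)),
        "density": traj.ravel(),
    })
    return TimeSeriesTable(records)


def observe(latent: TimeSeriesTable, obs: ObservationParams) -> TimeSeriesTable:
    """Apply the subsample-counting observation model to latent densities."""
    df = latent.df.copy()
    if obs.counting_noise == "none":
        return TimeSeriesTable(df, validate=False)
    rng = np.random.default_rng(obs.seed)
    mean_counts = df["density"].to_numpy() * obs.subsample_volume_ml
    counts = rng.poisson(mean_counts[:, None], size=(len(df), obs.n_subsamples))
    df["density"] = counts.mean(axis=1) / obs.subsample_volume_ml
    return TimeSeriesTable(df, validate=False)


def generate_study(
    params_by_treatment: dict[str, SimParams],
    obs: ObservationParams | None = None,
    replicates: int = 4,
    seed: int = 0,
) -> TimeSeriesTable:
    """Full multi-treatment observed dataset; replicates differ only by seed.

    Per-microcosm seeds are derived deterministically from ``seed`` via
    ``numpy.random.SeedSequence`` so the whole study is reproducible from
    one integer.
    """
    import dataclasses

    missing = [c for c in TREATMENT_ORDER if c not in params_by_treatment]
    if missing:
        raise ValueError(f"missing SimParams for treatment(s) {missing}")
    design = generate_design(replicates)
    frames = []
    for unit_index, (microcosm_id, treatment, rep) in enumerate(design):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(unit_index,))
        sim_seed, obs_seed = [int(s) for s in ss.generate_state(2) % (2**31)]
        params = dataclasses.replace(params_by_treatment[treatment.code], seed=sim_seed)
        latent = simulate_community(params, microcosm_id=microcosm_id, replicate=rep)
        if obs is not None:
            observed = observe(latent, dataclasses.replace(obs, seed=obs_seed))
        else:
            observed = latent
        frames.append(observed.df)
    return TimeSeriesTable(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Default study configuration
# ---------------------------------------------------------------------------

#: Monoculture carrying capacities (individuals/mL). Small-bodied ciliates
#: reach thousands per mL, the large Spirostomum only tens; the predator's
#: ceiling is low because it is limited by prey, not bacteria.
DEFAULT_CARRYING_CAPACITY = {"C": 1200.0, "D": 2500.0, "P": 120.0, "S": 40.0, "Pd": 20.0}

#: Intrinsic per-day growth-rate responses; stationarity is at 1/dt = 0.5,
#: so every species can grow from rarity (lambda > 0.5) except the predator,
#: which declines without prey.
DEFAULT_LAMBDA = {"C": 1.1, "D": 1.2, "P": 0.8, "S": 0.7, "Pd": 0.4}

#: Ten predator individuals pipetted into a 100 mL culture on days 4 and 8.
DEFAULT_PREDATOR_SCHEDULE = [(4.0, 10.0, 100.0), (8.0, 10.0, 100.0)]


def _self_limit(code: str, dt: float = 2.0) -> float:
    """alpha_ii placing the monoculture equilibrium at carrying capacity."""
    lam, k = DEFAULT_LAMBDA[code], DEFAULT_CARRYING_CAPACITY[code]
    return (lam - 1.0 / dt) / k


def _competition(i: str, j: str, strength: float, dt: float = 2.0) -> float:
    """alpha_ij such that N_j at its carrying capacity reduces species i's
    density-dependent response by ``strength`` times i's own maximum."""
    lam_i = DEFAULT_LAMBDA[i]
    return strength * (lam_i - 1.0 / dt) / DEFAULT_CARRYING_CAPACITY[j]


def default_study_params() -> dict[str, SimParams]:
    """Per-treatment SimParams emulating the experimental communities.

    Choices (documented in the methods note): the focal competitors are
    strongly asymmetric — Dexiostoma depresses Colpidium far more than the
    reverse, so Colpidium tends toward exclusion in the two-species
    community; third competitors interact weakly with the focal pair; the
    predator consumes all ciliates (strong positive alpha of prey on the
    predator's resource load is encoded as a negative coefficient, i.e.
    prey density raises the predator's growth). The CD community carries
    an intraspecific HOI of Dexiostoma on Colpidium's self-limitation,
    and the CDS community an interspecific HOI, so the synthetic study
    exercises every model family downstream.
    """
    params: dict[str, SimParams] = {}

    def alpha_block(codes: list[str]) -> dict[tuple[str, str], float]:
        strengths = {  # (focal i, neighbour j) -> relative competition
            ("C", "D"): 0.9, ("D", "C"): 0.25,
            ("C", "P"): 0.3, ("P", "C"): 0.3,
            ("D", "P"): 0.3, ("P", "D"): 0.3,
            ("C", "S"): 0.2, ("S", "C"): 0.2,
            ("D", "S"): 0.2, ("S", "D"): 0.2,
        }
        a: dict[tuple[str, str], float] = {}
        consumers = [c for c in codes if c != "Pd"]
        for i in consumers:
            a[(i, i)] = _self_limit(i)
            for j in consumers:
                if i != j:
                    a[(i, j)] = _competition(i, j, strengths[(i, j)])
        if "Pd" in codes:
            # explicit self-limitation: with saturating prey the predator
            # equilibrates at a few tens of individuals per mL
            a[("Pd", "Pd")] = 0.05
            for prey in consumers:
                # predation: predator density depresses prey growth ...
                a[(prey, "Pd")] = 0.6
                # ... while prey density fuels the predator (negative load).
                a[("Pd", prey)] = -0.8 / DEFAULT_CARRYING_CAPACITY[prey]
        return a

    for code in TREATMENT_ORDER:
        treatment = Treatment(code)
        codes = [sp.value for sp in treatment.species]
        lam = {c: DEFAULT_LAMBDA[c] for c in codes}
        alpha = alpha_block(codes)
        beta_intra: dict[tuple[str, str], float] = {}
        beta_inter: dict[tuple[str, str, str], float] = {}
        family, hoi = "LV", "none"
        base = treatment.competition_code
        if base == "CD":
            # Dexiostoma modifies Colpidium's self-limitation.
            family, hoi = "LV", "intra"
            beta_intra[("C", "D")] = 0.4 * alpha[("C", "D")] / DEFAULT_CARRYING_CAPACITY["D"]
        elif base == "CDP":
            family, hoi = "Ricker", "none"
            alpha = {k: _ricker_rescale(k, v) for k, v in alpha.items()}
            # predator coefficients act directly in the exponent; the
            # competitor equilibrium rescale does not apply to them
            for key, v in alpha_block(codes).items():
                if "Pd" in key:
                    alpha[key] = v
        elif base == "CDS":
            # Spirostomum softens the C-D interaction (interspecific HOI).
            family, hoi = "Ricker", "inter"
            alpha = {k: _ricker_rescale(k, v) for k, v in alpha.items()}
            # predator coefficients act directly in the exponent; the
            # competitor equilibrium rescale does not apply to them
            for key, v in alpha_block(codes).items():
                if "Pd" in key:
                    alpha[key] = v
            beta_inter[("C", "D", "S")] = -0.5 * alpha[("C", "D")] / DEFAULT_CARRYING_CAPACITY["S"]
            beta_inter[("D", "C", "S")] = -0.5 * alpha[("D", "C")] / DEFAULT_CARRYING_CAPACITY["S"]
        params[code] = SimParams(
            species=codes,
            lambda_=lam,
            alpha=alpha,
            beta_intra=beta_intra,
            beta_inter=beta_inter,
            family=family,
            hoi_structure=hoi,
            carrying_capacity={c: DEFAULT_CARRYING_CAPACITY[c] for c in codes},
            predator_schedule=DEFAULT_PREDATOR_SCHEDULE if treatment.predator_present else [],
        )
    return params


def _ricker_rescale(key: tuple[str, str], alpha_lv: float, dt: float = 2.0) -> float:
    """Convert an LV coefficient to a Ricker one preserving the monoculture
    equilibrium: lambda*exp(-a*K) = 1/dt requires a = ln(lambda*dt)/K."""
    i, j = key
    if i == j:
        lam, k = DEFAULT_LAMBDA[i], DEFAULT_CARRYING_CAPACITY[i]
        return np.log(lam * dt) / k
    # off-diagonal terms keep their strength relative to self-limitation
    lam, k = DEFAULT_LAMBDA[i], DEFAULT_CARRYING_CAPACITY[i]
    self_lv = _self_limit(i, dt)
    return (alpha_lv / self_lv) * np.log(lam * dt) / k if self_lv else alpha_lv
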