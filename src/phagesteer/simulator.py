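"""Stochastic serial-passage dynamics of E. coli and two lytic phages.

The engine emulates the wet experiment end to end: 4 mL batch cultures
inoculated with ~9e4 cells, dosed with ~1e6 PFU (MOI ~10), grown 24 h,
measured (OD600, phage spot assay), and diluted 1% into fresh medium daily.
Within a day, short-interval dynamics follow dN/dt = rN - phi*P*N per
genotype, extended with a shared carrying capacity K (so OD plateaus like a
real rich-medium culture) and burst-release of beta new particles per lysis.
Resistance evolves through a small genotype lattice: mutants differ in their
per-phage adsorption susceptibility s (1 = ancestral, 0 = fully resistant,
>1 = hypersensitive) and in a fractional growth cost c.

Numerics: Poisson tau-leaping at dt = 0.05 h for divisions (guarded so the
per-cell division probability per step stays <= 0.1), with infections drawn by
exact exponential-hazard binomial thinning Binomial(N, 1 - exp(-phi*s*P*dt/V))
— valid at any phage density, which matters because amplified phage reach
P/V ~ 1e9-1e10 per mL.  A deterministic-expectation mode propagates means
(midpoint rule for the logistic factor) for analytic tests.

The same parameter set drives simulated killing assays (30 min challenge with
~1e9 PFU of lysate, Poisson colony counting at a 30-300 colony dilution) and
5-min-resolution 24 h growth curves, so every measurement the downstream
statistics consume can be generated synthetically.
"""

from __future__ import annotations

import copy
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numba
import numpy as np

from .design import DoseEvent, TreatmentSpec, dose_schedule
from .resistance import KillingAssayRecord

__all__ = [
    "PHAGES",
    "Genotype",
    "SimParams",
    "PopulationState",
    "Trajectory",
    "StepSizeError",
    "ExtinctPopulationError",
    "default_genotypes",
    "default_mutations",
    "grow_and_infect",
    "daily_transfer",
    "apply_dose",
    "run_population",
    "run_design",
    "cfu_to_od",
    "od_to_cfu",
    "phage_presence",
    "simulate_killing_assay",
    "simulate_growth_curve",
    "sample_isolates",
    "cross_resistant_labels",
    "first_majority_day",
    "population_seed",
]

PHAGES: tuple[str, str] = ("T2", "LAMBDA")


class StepSizeError(RuntimeError):
    """Tau-leap step means too large; reduce ``dt_hours``."""


class ExtinctPopulationError(RuntimeError):
    """Requested isolates from an extinct population/day."""


@dataclass
class Genotype:
    """A bacterial genotype class: per-phage susceptibility multipliers and a
    fractional growth cost.  ``mucoid`` marks exopolysaccharide shielding
    phenotypes (matters only for labelling/reporting)."""

    label: str
    susceptibility: dict[str, float]
    growth_cost: float = 0.0
    mucoid: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.growth_cost < 1.0):
            raise ValueError(f"{self.label}: growth_cost must be in [0, 1)")
        for phage, s in self.susceptibility.items():
            if s < 0:
                raise ValueError(f"{self.label}: susceptibility[{phage}] must be >= 0")


def default_genotypes() -> tuple[Genotype, ...]:
    """Default genotype lattice.

    sensitive          ancestral (s = 1 both phages, no cost)
    t2_resistant       strong but partial T2-specific resistance (s = 0.05)
                       that is collaterally hypersensitive to lambda
                       (s = 6), no cost; T2 holds it in a below-detection
                       quasi-equilibrium that keeps feeding free T2
                       particles, and lambda — when present — crushes it
    cross_resistant    envZ-like regulatory downshift of the shared receptor:
                       near-complete escape from both phages (s = 3e-5), no
                       cost
    mucoid             igaA/rcsD- or csrA-like exopolysaccharide shielding:
                       near-complete escape from both phages, 15% growth cost
    lambda_resistant   lambda-specific partial loss, no cost
    """
    return (
        Genotype("sensitive", {"T2": 1.0, "LAMBDA": 1.0}),
        Genotype("t2_resistant", {"T2": 0.05, "LAMBDA": 6.0}),
        Genotype("cross_resistant", {"T2": 3e-5, "LAMBDA": 3e-5}),
        Genotype("mucoid", {"T2": 3e-5, "LAMBDA": 3e-5}, growth_cost=0.15, mucoid=True),
        Genotype("lambda_resistant", {"T2": 1.0, "LAMBDA": 0.5}),
    )


def default_mutations() -> dict[tuple[str, str], float]:
    """Per-division mutation probabilities between genotype classes.

    T2-specific resistance is by far the most accessible route (3e-7); the
    full-escape cross-resistant routes are two orders of magnitude rarer
    (3e-9 regulatory, 6e-10 mucoid); weak lambda-specific partial loss is
    rare too (5e-10).  A rare second-hit route t2_resistant ->
    cross_resistant (1e-10) lets T2-resistant backgrounds acquire lambda
    resistance late, as happens in T2-first treatments.
    """
    return {
        ("sensitive", "t2_resistant"): 3e-7,
        ("sensitive", "cross_resistant"): 3e-9,
        ("sensitive", "mucoid"): 6e-10,
        ("sensitive", "lambda_resistant"): 5e-10,
        ("t2_resistant", "cross_resistant"): 1e-10,
    }


@dataclass
class SimParams:
    """All tunable parameters of the synthetic experiment.

    Rates are per hour, densities per mL, volumes in mL, counts absolute.
    ``phi`` is the adsorption-rate constant (mL particle^-1 h^-1); T2 is the
    stronger phage.  ``od_max``/``n_half`` define the saturating OD600
    calibration OD = od_max * N / (N + n_half).  ``deterministic`` switches
    every stochastic draw to its expectation (analytic-test mode).
    """

    r: float = 1.2                      # max specific growth rate, h^-1
    K: float = 2e9                      # carrying capacity, cells/mL
    phi: dict[str, float] = field(default_factory=lambda: {"T2": 8e-8, "LAMBDA": 8e-8})
    burst: dict[str, float] = field(default_factory=lambda: {"T2": 50.0, "LAMBDA": 3.0})
    decay: dict[str, float] = field(default_factory=lambda: {"T2": 0.6, "LAMBDA": 0.6})
    genotypes: tuple[Genotype, ...] = field(default_factory=default_genotypes)
    mutations: dict[tuple[str, str], float] = field(default_factory=default_mutations)
    collateral_prob: float = 0.3        # chance the T2-specific route is collaterally lambda-sensitive
    collateral_s_lambda: float = 1.5
    refuge_cells: float = 4e6           # wall-population refuge: total cells shielded from phage
    dormant_on: float = 0.01            # bulk -> dormant persister switching, h^-1
    dormant_off: float = 0.05           # dormant -> bulk resuscitation, h^-1
    dilution: float = 0.01              # daily transfer fraction (40 uL into 4 mL)
    volume_ml: float = 4.0
    dt_hours: float = 0.05
    detection_od: float = 0.01
    od_max: float = 1.5
    n_half: float = 1e9                 # cells/mL at half-maximal OD
    inoculum_cfu: float = 9e4
    dose_pfu: float = 1e6
    presence_threshold: float = 1e3     # free particles/mL scored as "present"
    assay_duration_h: float = 0.5
    assay_lysate_pfu: float = 1e9       # total PFU added per killing-assay tube
    assay_volume_ml: float = 4.1
    assay_prep_density: float = 2.5e6   # cells/mL after the 2 h outgrowth
    plate_volume_ml: float = 0.1
    plate_max_colonies: float = 300.0
    resistant_adsorption: bool = False  # if True, fully resistant cells still soak up particles
    deterministic: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.dilution < 1.0):
            raise ValueError("dilution must be in (0, 1)")
        if not (0.0 < self.dt_hours <= 0.1):
            raise ValueError("dt_hours must be in (0, 0.1]")
        for name in ("r", "K", "volume_ml", "od_max", "n_half", "dormant_on", "dormant_off"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for mapping in (self.phi, self.burst, self.decay):
            for phage, value in mapping.items():
                if value < 0:
                    raise ValueError(f"negative rate for phage {phage}")
        labels = [g.label for g in self.genotypes]
        if len(set(labels)) != len(labels):
            raise ValueError("genotype labels must be unique")
        outgoing: dict[str, float] = {}
        for (src, dst), mu in self.mutations.items():
            if mu < 0:
                raise ValueError("mutation probabilities must be >= 0")
            if src not in labels or dst not in labels:
                raise ValueError(f"mutation route {src}->{dst} references unknown genotype")
            outgoing[src] = outgoing.get(src, 0.0) + mu
        if outgoing and max(outgoing.values()) >= 1e-3:
            raise ValueError("total outgoing mutation probability per division must be < 1e-3")

    def genotype(self, label: str) -> Genotype:
        for g in self.genotypes:
            if g.label == label:
                return g
        raise KeyError(label)


@dataclass
class PopulationState:
    """Cell counts per genotype and free-particle counts per phage in one
    culture, at elapsed time ``t_hours``.  ``dormant`` holds the
    phage-inaccessible persister subpopulation per genotype (non-growing,
    transferred like any other cell)."""

    t_hours: float
    cells: dict[str, int]
    phage: dict[str, int]
    dormant: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mapping in (self.cells, self.phage, self.dormant):
            for key, count in mapping.items():
                if count < 0:
                    raise ValueError(f"negative count for {key}")

    @property
    def total_cells(self) -> int:
        return int(sum(self.cells.values())) + int(sum(self.dormant.values()))

    @property
    def extinct(self) -> bool:
        return self.total_cells == 0


@dataclass
class Trajectory:
    """Daily observations of one serial-passage population.

    ``od600`` is recorded after within-day growth, before transfer; values
    below the optical detection limit are stored at the limit with
    ``censored`` set.  ``genotypes`` is the realized per-run genotype set
    (the collateral-sensitivity draw is resolved per population).
    """

    population_id: str
    seed: int
    days: np.ndarray
    od600: np.ndarray
    censored: np.ndarray
    phage_present: dict[str, np.ndarray]
    genotype_frequencies: list[dict[str, float]]
    extinction_day: int | None
    dose_log: list[dict]
    genotypes: tuple[Genotype, ...]

    def mean_od(self) -> float:
        """Mean OD600 across the experiment (censored values at the limit)."""
        return float(np.mean(self.od600))


# ---------------------------------------------------------------------------
# RNG plumbing

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def population_seed(seed: int, population_id: str) -> np.random.SeedSequence:
    """Fan a single experiment seed out to a per-population stream by stable
    hashing of the population id (order-independent, reproducible)."""
    return np.random.SeedSequence([int(seed), zlib.crc32(population_id.encode())])


# ---------------------------------------------------------------------------
# OD calibration

def cfu_to_od(n_cells_per_ml: float, params: SimParams) -> float:
    """Saturating OD600 calibration OD = od_max * N / (N + n_half)."""
    n = np.asarray(n_cells_per_ml, dtype=float)
    od = params.od_max * n / (n + params.n_half)
    return od if od.ndim else float(od)


def od_to_cfu(od600: float, params: SimParams) -> float:
    """Inverse calibration, defined for 0 <= OD < od_max."""
    od = np.asarray(od600, dtype=float)
    if np.any(od < 0) or np.any(od >= params.od_max):
        raise ValueError(f"OD must lie in [0, od_max={params.od_max})")
    n = params.n_half * od / (params.od_max - od)
    return n if n.ndim else float(n)


def phage_presence(
    state: PopulationState, params: SimParams, threshold_pfu_per_ml: float | None = None
) -> dict[str, bool]:
    """Thresholded spot-assay analogue: present iff free particles per mL
    reach the detection threshold (default 1e3)."""
    threshold = params.presence_threshold if threshold_pfu_per_ml is None else threshold_pfu_per_ml
    return {
        phage: (state.phage.get(phage, 0) / params.volume_ml) >= threshold
        for phage in PHAGES
    }


# ---------------------------------------------------------------------------
# Core dynamics

class _Kernel:
    """Precomputed arrays for the inner step loop of one parameter set."""

    def __init__(self, params: SimParams):
        self.params = params
        self.labels = [g.label for g in params.genotypes]
        self.index = {lbl: i for i, lbl in enumerate(self.labels)}
        n_gen = len(self.labels)
        self.growth = params.r * np.array([1.0 - g.growth_cost for g in params.genotypes])
        self.S = np.array(
            [[g.susceptibility.get(p, 1.0) for p in PHAGES] for g in params.genotypes]
        )
        self.phi = np.array([params.phi.get(p, 0.0) for p in PHAGES])
        self.burst = np.array([params.burst.get(p, 0.0) for p in PHAGES])
        self.decay = np.array([params.decay.get(p, 0.0) for p in PHAGES])
        src, dst, rate = [], [], []
        for (a, b), mu in params.mutations.items():
            if mu > 0:
                src.append(self.index[a])
                dst.append(self.index[b])
                rate.append(mu)
        self.mut_src = np.array(src, dtype=np.int64)
        self.mut_dst = np.array(dst, dtype=np.int64)
        self.mut_rate = np.array(rate, dtype=np.float64)
        self.burst1 = self.burst.astype(np.int64) - 1
        self.phi_v = self.phi / params.volume_ml
        self.KV = params.K * params.volume_ml  # total carrying capacity, cells
        self.V = params.volume_ml
        self.refuge = params.refuge_cells
        self.kon = params.dormant_on
        self.koff = params.dormant_off

    def cells_array(self, cells: Mapping[str, int], dtype) -> np.ndarray:
        arr = np.zeros(len(self.labels), dtype=dtype)
        for lbl, count in cells.items():
            arr[self.index[lbl]] = count
        return arr

    def phage_array(self, phage: Mapping[str, int], dtype) -> np.ndarray:
        return np.array([phage.get(p, 0) for p in PHAGES], dtype=dtype)


@numba.njit(cache=True)
def _advance_stochastic(
    n, d, p, growth, S, phi_v, burst1, decay, mut_src, mut_dst, mut_rate,
    KV, refuge, kon, koff, soak, n_steps, dt, last_dt, seed,
):  # pragma: no cover - exercised via grow_and_infect
    """Tau-leap the within-day dynamics over ``n_steps`` steps in place.

    Divisions: Poisson with mean r(1-c)(1-N/K)N dt.  Infections: exact
    exponential-hazard binomial thinning of the refuge-exposed excess.  Each
    infection removes the cell and the adsorbed particle and releases
    ``burst`` new particles within the same step.  Free phage decay by
    exponential thinning.  Mutations ride on divisions.  ``d`` holds the
    dormant persister pool per genotype: non-growing, phage-inaccessible,
    exchanging with the bulk at rates kon/koff.
    """
    np.random.seed(seed)
    n_gen = n.shape[0]
    n_ph = p.shape[0]
    div = np.zeros(n_gen, dtype=np.int64)
    inf_by_phage = np.zeros(n_ph, dtype=np.int64)
    for step in range(n_steps):
        h = dt if step < n_steps - 1 else last_dt
        ntot = 0
        for i in range(n_gen):
            ntot += n[i] + d[i]
        if ntot > 0:
            logistic = 1.0 - ntot / KV
            if logistic < 0.0:
                logistic = 0.0
            # wall-refuge: only the excess above the shared floor is exposed
            exposed = 1.0 - refuge / ntot
            if exposed < 0.0:
                exposed = 0.0
            for j in range(n_ph):
                inf_by_phage[j] = 0
            for i in range(n_gen):
                ni = n[i]
                if ni <= 0:
                    div[i] = 0
                    continue
                lam = growth[i] * logistic * h * ni
                div[i] = np.random.poisson(lam) if lam > 0.0 else 0
                w0 = S[i, 0] * phi_v[0] * p[0]
                w1 = S[i, 1] * phi_v[1] * p[1] if n_ph > 1 else 0.0
                wsum = w0 + w1
                infected = 0
                if wsum > 0.0 and exposed > 0.0:
                    frac = -np.expm1(-wsum * exposed * h)
                    infected = np.random.binomial(ni, frac)
                    if infected > 0:
                        if w1 == 0.0:
                            inf0 = infected
                        elif w0 == 0.0:
                            inf0 = 0
                        else:
                            inf0 = np.random.binomial(infected, w0 / wsum)
                        inf_by_phage[0] += inf0
                        if n_ph > 1:
                            inf_by_phage[1] += infected - inf0
                n[i] = ni + div[i] - infected
            for k in range(mut_src.shape[0]):
                src_div = div[mut_src[k]]
                if src_div > 0:
                    m = np.random.poisson(src_div * mut_rate[k])
                    if m > 0:
                        n[mut_src[k]] -= m
                        n[mut_dst[k]] += m
            for i in range(n_gen):
                if n[i] < 0:
                    n[i] = 0
        if kon > 0.0 or koff > 0.0:
            for i in range(n_gen):
                on = np.random.binomial(n[i], -np.expm1(-kon * h)) if n[i] > 0 else 0
                off = np.random.binomial(d[i], -np.expm1(-koff * h)) if d[i] > 0 else 0
                n[i] += off - on
                d[i] += on - off
        for j in range(n_ph):
            pj = p[j] + inf_by_phage[j] * burst1[j]
            if pj > 0:
                if soak:
                    res = 0
                    for i in range(n_gen):
                        if S[i, j] == 0.0:
                            res += n[i]
                    if res > 0:
                        pj -= np.random.binomial(pj, -np.expm1(-phi_v[j] * res * h))
                if decay[j] > 0.0:
                    pj -= np.random.binomial(pj, -np.expm1(-decay[j] * h))
            if pj < 0:
                pj = 0
            p[j] = pj
            inf_by_phage[j] = 0


def _step_deterministic(kern: _Kernel, n, d, p, dt):
    ntot = n.sum() + d.sum()
    if ntot == 0:
        return n, d, p * np.exp(-kern.decay * dt)
    exposed = max(0.0, 1.0 - kern.refuge / ntot) if ntot > 0 else 0.0
    hazard = kern.S @ (kern.phi * (p / kern.V)) * exposed
    # midpoint rule on the logistic factor; growth/killing exact within step
    k1 = kern.growth * max(0.0, 1.0 - ntot / kern.KV) - hazard
    n_half = n * np.exp(0.5 * dt * k1)
    k2 = kern.growth * max(0.0, 1.0 - n_half.sum() / kern.KV) - hazard
    infected = n * (-np.expm1(-hazard * dt))
    weights = kern.S * (kern.phi * (p / kern.V))
    wsum = weights.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(
            wsum[:, None] > 0, weights / np.where(wsum[:, None] > 0, wsum[:, None], 1.0), 0.0
        )
    by_phage = (infected[:, None] * share).sum(axis=0)
    n = n * np.exp(dt * k2)
    if kern.mut_src.size:
        div = n * kern.growth * max(0.0, 1.0 - ntot / kern.KV) * dt
        mut = div[kern.mut_src] * kern.mut_rate
        np.subtract.at(n, kern.mut_src, mut)
        np.add.at(n, kern.mut_dst, mut)
        np.maximum(n, 0.0, out=n)
    if kern.kon > 0.0 or kern.koff > 0.0:
        on = n * (-np.expm1(-kern.kon * dt))
        off = d * (-np.expm1(-kern.koff * dt))
        n = n + off - on
        d = d + on - off
    p = p + by_phage * (kern.burst - 1.0)
    p = p * np.exp(-kern.decay * dt)
    np.maximum(p, 0.0, out=p)
    return n, d, p


def grow_and_infect(
    state: PopulationState,
    params: SimParams,
    hours: float,
    rng_seed=None,
) -> PopulationState:
    """Advance within-day growth/infection dynamics by ``hours``.

    Stochastic mode draws divisions as Poisson tau-leaps (per-cell division
    probability per step must stay <= 0.1, else :class:`StepSizeError`) and
    infections as exact exponential-hazard binomials; each infection removes
    the cell and the adsorbed particle and releases ``burst`` new particles
    within the same step (no explicit latent period).  Deterministic mode
    propagates expectations.
    """
    if hours <= 0:
        raise ValueError("hours must be > 0")
    kern = _Kernel(params)
    dt = params.dt_hours
    if kern.growth.max(initial=0.0) * dt > 0.1:
        raise StepSizeError(
            f"per-cell division mean r*dt = {kern.growth.max() * dt:.3f} exceeds 0.1; "
            "reduce dt_hours for a valid tau-leap"
        )
    n_steps = int(math.ceil(hours / dt - 1e-9))
    last_dt = hours - dt * (n_steps - 1)

    if params.deterministic:
        n = kern.cells_array(state.cells, float)
        d = kern.cells_array(state.dormant, float)
        p = kern.phage_array(state.phage, float)
        for i in range(n_steps):
            n, d, p = _step_deterministic(kern, n, d, p, dt if i < n_steps - 1 else last_dt)
        cells = {lbl: int(round(n[i])) for i, lbl in enumerate(kern.labels)}
        dormant = {lbl: int(round(d[i])) for i, lbl in enumerate(kern.labels)}
        phage = {ph: int(round(p[j])) for j, ph in enumerate(PHAGES)}
    else:
        rng = _as_rng(rng_seed)
        n = kern.cells_array(state.cells, np.int64)
        d = kern.cells_array(state.dormant, np.int64)
        p = kern.phage_array(state.phage, np.int64)
        _advance_stochastic(
            n, d, p, kern.growth, kern.S, kern.phi_v, kern.burst1, kern.decay,
            kern.mut_src, kern.mut_dst, kern.mut_rate, kern.KV, kern.refuge,
            kern.kon, kern.koff, params.resistant_adsorption, n_steps, dt, last_dt,
            int(rng.integers(1 << 31)),
        )
        cells = {lbl: int(n[i]) for i, lbl in enumerate(kern.labels)}
        dormant = {lbl: int(d[i]) for i, lbl in enumerate(kern.labels)}
        phage = {ph: int(p[j]) for j, ph in enumerate(PHAGES)}
    return PopulationState(state.t_hours + hours, cells, phage, dormant)


def daily_transfer(state: PopulationState, params: SimParams, rng_seed=None) -> PopulationState:
    """1% serial transfer: each cell and particle count is thinned
    Binomial(count, D) (deterministic mode: round(D * count))."""
    D = params.dilution
    if params.deterministic:
        thin = lambda c: int(round(D * c))
    else:
        rng = _as_rng(rng_seed)
        thin = lambda c: int(rng.binomial(c, D))
    cells = {lbl: thin(c) for lbl, c in state.cells.items()}
    phage = {ph: thin(c) for ph, c in state.phage.items()}
    dormant = {lbl: thin(c) for lbl, c in state.dormant.items()}
    return PopulationState(state.t_hours, cells, phage, dormant)


def apply_dose(state: PopulationState, dose: DoseEvent) -> tuple[PopulationState, float]:
    """Add dose PFU to the free-phage pools; returns the new state and the
    realized multiplicity of infection (added PFU / current total cells)."""
    phage = dict(state.phage)
    for ph, pfu in dose.pfu_by_phage.items():
        phage[ph] = phage.get(ph, 0) + int(round(pfu))
    total = state.total_cells
    moi = dose.total_pfu / total if total > 0 else math.inf
    return (
        PopulationState(state.t_hours, dict(state.cells), phage, dict(state.dormant)),
        moi,
    )


def _resolve_collateral(params: SimParams, rng: np.random.Generator) -> SimParams:
    """Per-population draw: a T2-specific genotype whose lambda
    susceptibility is still ancestral (s = 1) becomes collaterally
    hypersensitive with probability ``collateral_prob``.  The default
    lattice's T2-specific genotype is already hypersensitive, so the draw
    only matters for custom lattices."""
    genotypes = tuple(copy.deepcopy(g) for g in params.genotypes)
    draw = None
    for g in genotypes:
        if g.susceptibility.get("T2", 1.0) < 1.0 and g.susceptibility.get("LAMBDA", 1.0) == 1.0:
            if draw is None:
                draw = rng.random() < params.collateral_prob
            if draw:
                g.susceptibility["LAMBDA"] = params.collateral_s_lambda
    return replace(params, genotypes=genotypes)


def run_population(
    spec: TreatmentSpec,
    params: SimParams,
    seed: int,
    population_id: str | None = None,
) -> Trajectory:
    """Simulate one serial-passage population under a treatment arm.

    Day loop: apply any scheduled dose, grow/infect for 24 h, record (OD600,
    phage presence, genotype frequencies), then transfer 1% into fresh medium.
    Reproducible given (spec, params, seed, population_id).
    """
    pid = population_id or f"{spec.label}_r1"
    rng = np.random.default_rng(population_seed(seed, pid))
    params_run = _resolve_collateral(params, rng)
    doses = {ev.day: ev for ev in dose_schedule(spec, params.dose_pfu)}
    sensitive = params_run.genotypes[0].label
    state = PopulationState(
        0.0, {sensitive: int(params.inoculum_cfu)}, {ph: 0 for ph in PHAGES}
    )

    days, ods, censored = [], [], []
    present: dict[str, list[bool]] = {ph: [] for ph in PHAGES}
    freqs: list[dict[str, float]] = []
    dose_log: list[dict] = []
    extinction_day: int | None = None

    for d in range(spec.duration_days):
        if d in doses:
            state, moi = apply_dose(state, doses[d])
            dose_log.append(
                {"day": d, "pfu_by_phage": dict(doses[d].pfu_by_phage), "moi": moi}
            )
        state = grow_and_infect(state, params_run, 24.0, rng)

        density = state.total_cells / params.volume_ml
        od_raw = cfu_to_od(density, params)
        is_censored = od_raw < params.detection_od
        days.append(d + 1)
        ods.append(params.detection_od if is_censored else od_raw)
        censored.append(is_censored)
        for ph, flag in phage_presence(state, params).items():
            present[ph].append(flag)
        total = state.total_cells
        combined: dict[str, int] = dict(state.cells)
        for lbl, c in state.dormant.items():
            combined[lbl] = combined.get(lbl, 0) + c
        freqs.append(
            {lbl: c / total for lbl, c in combined.items() if c > 0} if total else {}
        )
        if total == 0 and extinction_day is None:
            extinction_day = d + 1

        state = daily_transfer(state, params_run, rng)
        if state.extinct and extinction_day is None:
            extinction_day = d + 1

    return Trajectory(
        population_id=pid,
        seed=seed,
        days=np.array(days),
        od600=np.array(ods),
        censored=np.array(censored),
        phage_present={ph: np.array(v) for ph, v in present.items()},
        genotype_frequencies=freqs,
        extinction_day=extinction_day,
        dose_log=dose_log,
        genotypes=params_run.genotypes,
    )


def run_design(
    arms: Iterable[TreatmentSpec], params: SimParams, seed: int
) -> list[Trajectory]:
    """Simulate every replicate population of a design (arms in order,
    replicates 1..n); per-population streams are derived from the single
    experiment seed, so the result is order-independent."""
    trajectories = []
    for spec in arms:
        for k in range(1, spec.n_replicates + 1):
            pid = f"{spec.label}_r{k}"
            trajectories.append(run_population(spec, params, seed, population_id=pid))
    return trajectories


# ---------------------------------------------------------------------------
# Simulated measurements

def _plate_count(density: float, params: SimParams, rng) -> tuple[float, bool]:
    """Poisson colony counting at a serial dilution targeting 30-300 colonies.

    Returns (estimated CFU/mL, below_detection).  If even the undiluted plate
    expects < 1 colony the record is flagged and imputed at the plating limit
    (one colony per plate volume)."""
    expected_undiluted = density * params.plate_volume_ml
    limit = 1.0 / params.plate_volume_ml
    if expected_undiluted < 1.0:
        return limit, True
    k = max(0, int(math.ceil(math.log10(expected_undiluted / params.plate_max_colonies))))
    expected = expected_undiluted / 10.0**k
    if params.deterministic:
        colonies = expected
    else:
        colonies = rng.poisson(expected)
    if colonies == 0:
        return limit * 10.0**k, True
    return colonies * 10.0**k / params.plate_volume_ml, False


def simulate_killing_assay(
    genotype: Genotype,
    phage: str,
    params: SimParams,
    seed=None,
    isolate_id: str | None = None,
    day: int = 0,
    replicate_index: int = 1,
) -> KillingAssayRecord:
    """Simulate one liquid killing assay (isolate + paired wild-type control).

    Both arms start from the standard assay prep (~2.5e6 cells/mL after a 2 h
    outgrowth) and run 30 min.  The no-phage arm grows exponentially at
    r(1-c); the phage arm follows N(t) = N0 exp((r(1-c) - phi*s*P/V) t) with
    ~1e9 PFU of lysate.  Densities are then plated (Poisson colony noise at a
    30-300 colony dilution) and converted back to CFU/mL.
    """
    if phage not in PHAGES:
        raise ValueError(f"unknown phage {phage!r}")
    rng = _as_rng(seed)
    t = params.assay_duration_h
    p_per_ml = params.assay_lysate_pfu / params.assay_volume_ml

    def densities(s: float, cost: float) -> tuple[float, float]:
        n_np = params.assay_prep_density * math.exp(params.r * (1.0 - cost) * t)
        n_p = n_np * math.exp(-params.phi[phage] * s * p_per_ml * t)
        return n_p, n_np

    iso_p_true, iso_np_true = densities(genotype.susceptibility.get(phage, 1.0), genotype.growth_cost)
    wt_p_true, wt_np_true = densities(1.0, 0.0)
    iso_p, flag_p = _plate_count(iso_p_true, params, rng)
    iso_np, _ = _plate_count(iso_np_true, params, rng)
    wt_p, _ = _plate_count(wt_p_true, params, rng)
    wt_np, _ = _plate_count(wt_np_true, params, rng)
    return KillingAssayRecord(
        isolate_id=isolate_id or genotype.label,
        day=day,
        phage=phage,
        iso_p=iso_p,
        iso_np=iso_np,
        wt_p=wt_p,
        wt_np=wt_np,
        replicate_index=replicate_index,
        below_detection=flag_p,
    )


def simulate_growth_curve(
    genotype: Genotype,
    params: SimParams,
    noise_sd: float = 0.0,
    seed=None,
    lag_hours: float = 0.0,
    n_points: int = 289,
    interval_min: float = 5.0,
    blank: float = 0.0,
):
    """Simulate a 24 h microplate growth curve (5-min grid, 289 points).

    Logistic growth at rate r(1-c) from the standard prep density, an optional
    lag, conversion through the OD calibration, an additive blank, and
    multiplicative log-normal noise of the stated sd.  Returns
    ``(times_min, od600)`` arrays.
    """
    rng = _as_rng(seed)
    times_min = np.arange(n_points) * interval_min
    t = np.maximum(times_min / 60.0 - lag_hours, 0.0)
    g = params.r * (1.0 - genotype.growth_cost)
    n0, K = params.assay_prep_density, params.K
    growth = np.exp(g * t)
    n = K * n0 * growth / (K + n0 * (growth - 1.0))
    od = cfu_to_od(n, params) + blank
    if noise_sd > 0:
        od = od * np.exp(rng.normal(0.0, noise_sd, size=od.shape))
    return times_min, od


def sample_isolates(
    trajectory: Trajectory, day: int, n: int, seed=None
) -> list[Genotype]:
    """Draw ``n`` colony isolates from a population's recorded genotype
    frequencies on a sampling day (multinomial)."""
    rng = _as_rng(seed)
    idx = list(trajectory.days).index(day)
    freqs = trajectory.genotype_frequencies[idx]
    if not freqs:
        raise ExtinctPopulationError(
            f"{trajectory.population_id}: population extinct on day {day}"
        )
    labels = sorted(freqs)
    probs = np.array([freqs[lbl] for lbl in labels])
    probs = probs / probs.sum()
    counts = rng.multinomial(n, probs)
    by_label = {g.label: g for g in trajectory.genotypes}
    isolates: list[Genotype] = []
    for lbl, count in zip(labels, counts):
        isolates.extend(copy.deepcopy(by_label[lbl]) for _ in range(count))
    return isolates


# ---------------------------------------------------------------------------
# Summaries used by the steering analyses

def cross_resistant_labels(genotypes: Sequence[Genotype]) -> list[str]:
    """Genotypes with reduced susceptibility to both phages."""
    return [
        g.label
        for g in genotypes
        if all(g.susceptibility.get(p, 1.0) < 1.0 for p in PHAGES)
    ]


def first_majority_day(trajectory: Trajectory, labels: Iterable[str] | None = None,
                       threshold: float = 0.5) -> int | None:
    """First recorded day on which the summed frequency of ``labels``
    (default: cross-resistant genotypes) exceeds ``threshold``; None if
    never."""
    if labels is None:
        labels = cross_resistant_labels(trajectory.genotypes)
    labels = set(labels)
    for day, freqs in zip(trajectory.days, trajectory.genotype_frequencies):
        if sum(freqs.get(lbl, 0.0) for lbl in labels) > threshold:
            return int(day)
    return None
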