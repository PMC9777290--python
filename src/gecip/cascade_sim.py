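"""Mass-action models of multi-level phosphorylation cascades.

A cascade is a chain of proteins — receptor, intracellular kinase, target —
each existing in un-, mono- and dual-phosphorylated states. Every reaction
moves one molecule of a protein between two of its own phosphorylation
states, optionally catalysed by a modifier (the extracellular signal or the
active form of an upstream protein), so the total amount of each protein is
conserved along every trajectory. Dynamics follow mass-action kinetics:

    dx_i/dt = sum(production rates) - sum(consumption rates)

with each reaction rate = kpar * [substrate] * [modifier] (the modifier
factor is the input-signal strength for receptor activation, 1 for plain
first-order dephosphorylation).

A cascade is scored against six input signals spanning five orders of
magnitude. For each signal the dual-phosphorylated target protein (ppTP) is
integrated over a fixed time grid; if its fraction of the total target-protein
pool exceeds the threshold level TL = 1/10 at any grid point, the cascade
earns a per-signal fitness factor: 1.0 in single-cascade mode, 0.5 per
responsive cascade in two-cascade crosstalk mode. The overall fitness F is
the mean of the per-signal factors over the six signals, so F is always in
[0, 1].

Kinetic parameters are optimised by a (mu + lambda)-style evolutionary
algorithm: 200 cascades with random rates, the best 50 kept each generation,
four copies of each survivor (one elite copy unmutated, three mutated)
refilling the population, for 200 generations.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.integrate import odeint, solve_ivp

#: Six input-signal strengths used for every fitness evaluation.
SIGNALS: tuple[float, ...] = (0.0001, 0.001, 0.01, 0.1, 1.0, 10.0)

#: Initial (and, by conservation, total) pool of each protein, in a.u.
DEFAULT_POOL = 10.0

#: Threshold level: ppTP fraction of the total target pool that makes a
#: cascade responsive for a signal.
THRESHOLD_FRACTION = 0.1

SIGNAL_MODIFIER = "signal"


class TopologyError(ValueError):
    """A topology specification violates a structural constraint."""


@dataclass(frozen=True)
class Reaction:
    """One interconversion ``substrate -> product`` within a protein.

    ``modifier`` names the catalysing species, or ``"signal"`` for the
    external input, or ``None`` for a plain first-order step. ``rate`` is the
    identifier of the kinetic parameter (several reactions may share one).
    """

    substrate: str
    product: str
    rate: str
    modifier: str | None = None


@dataclass
class CascadeModel:
    """A fully specified cascade: structure plus kinetic parameters.

    proteins maps each protein to its ordered state species (state 0 is the
    unphosphorylated form and holds the entire pool initially). outputs lists
    the dual-phosphorylated target species, one per cascade; its length
    selects single vs crosstalk fitness mode.
    """

    proteins: dict[str, tuple[str, ...]]
    reactions: tuple[Reaction, ...]
    kpar: dict[str, float]
    outputs: tuple[str, ...]
    pool: float = DEFAULT_POOL

    def __post_init__(self) -> None:
        self.species: tuple[str, ...] = tuple(
            s for states in self.proteins.values() for s in states
        )
        if len(set(self.species)) != len(self.species):
            raise TopologyError("duplicate species across proteins")
        self._index = {s: i for i, s in enumerate(self.species)}
        self._protein_of = {
            s: p for p, states in self.proteins.items() for s in states
        }
        self._validate()
        self._compiled: _Compiled | None = None

    def _validate(self) -> None:
        for r in self.reactions:
            for s in (r.substrate, r.product):
                if s not in self._index:
                    raise TopologyError(f"unknown species {s!r} in reaction {r}")
            if self._protein_of[r.substrate] != self._protein_of[r.product]:
                raise TopologyError(
                    f"reaction {r.substrate}->{r.product} converts between "
                    f"different proteins and would break conservation"
                )
            if r.modifier not in (None, SIGNAL_MODIFIER) and r.modifier not in self._index:
                raise TopologyError(f"unknown modifier {r.modifier!r} in reaction {r}")
            if r.rate not in self.kpar:
                raise TopologyError(f"no kinetic parameter for rate id {r.rate!r}")
        for rate_id, k in self.kpar.items():
            if k < 0:
                raise TopologyError(f"kpar[{rate_id!r}] must be >= 0, got {k}")
        for out in self.outputs:
            if out not in self._index:
                raise TopologyError(f"unknown output species {out!r}")

    # -- structure ---------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    def initial_state(self) -> np.ndarray:
        x0 = np.zeros(self.n_species)
        for states in self.proteins.values():
            x0[self._index[states[0]]] = self.pool
        return x0

    def interaction_matrix(self) -> np.ndarray:
        """Species x reactions stoichiometry with entries in {+1, -1, 0}."""
        mat = np.zeros((self.n_species, len(self.reactions)), dtype=int)
        for j, r in enumerate(self.reactions):
            mat[self._index[r.substrate], j] = -1
            mat[self._index[r.product], j] = +1
        return mat

    def protein_totals(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Per-protein summed concentration for a state vector or trajectory."""
        out = {}
        for p, states in self.proteins.items():
            idx = [self._index[s] for s in states]
            out[p] = np.asarray(x)[..., idx].sum(axis=-1)
        return out

    def with_kpar(self, kpar: dict[str, float]) -> "CascadeModel":
        return replace(self, kpar=dict(kpar))

    @property
    def rate_ids(self) -> tuple[str, ...]:
        # insertion order of the kpar mapping is the canonical rate ordering
        return tuple(self.kpar)

    def kpar_vector(self) -> np.ndarray:
        return np.array([self.kpar[r] for r in self.rate_ids], dtype=float)

    def compiled(self) -> "_Compiled":
        if self._compiled is None:
            self._compiled = _Compiled.from_model(self)
        return self._compiled


@dataclass
class _Compiled:
    """Index arrays for a fast vectorised right-hand side."""

    sub: np.ndarray          # substrate index per reaction
    mod_idx: np.ndarray      # modifier species index (0 where unused)
    mod_is_species: np.ndarray
    mod_is_signal: np.ndarray
    rate_slot: np.ndarray    # kpar-vector slot per reaction
    stoich: np.ndarray       # n_species x n_reactions, float
    out_idx: np.ndarray
    x0: np.ndarray

    @classmethod
    def from_model(cls, model: CascadeModel) -> "_Compiled":
        idx = model._index
        slot = {r: i for i, r in enumerate(model.rate_ids)}
        sub, mod_idx, is_spec, is_sig, rate_slot = [], [], [], [], []
        for r in model.reactions:
            sub.append(idx[r.substrate])
            is_sig.append(r.modifier == SIGNAL_MODIFIER)
            is_spec.append(r.modifier is not None and r.modifier != SIGNAL_MODIFIER)
            mod_idx.append(idx[r.modifier] if is_spec[-1] else 0)
            rate_slot.append(slot[r.rate])
        return cls(
            sub=np.array(sub),
            mod_idx=np.array(mod_idx),
            mod_is_species=np.array(is_spec, dtype=bool),
            mod_is_signal=np.array(is_sig, dtype=bool),
            rate_slot=np.array(rate_slot),
            stoich=model.interaction_matrix().astype(float),
            out_idx=np.array([idx[o] for o in model.outputs]),
            x0=model.initial_state(),
        )

    def rate_constants(self, kvec: np.ndarray) -> np.ndarray:
        """Per-reaction constants, with the signal folded in by the caller."""
        return np.asarray(kvec)[..., self.rate_slot]


# ---------------------------------------------------------------------------
# topology specifications (plain dicts, YAML round-trippable)
# ---------------------------------------------------------------------------

def build_cascade(
    topology: dict,
    kpar: dict[str, float] | None = None,
    verify_inactive: bool = True,
) -> CascadeModel:
    """Instantiate a :class:`CascadeModel` from a topology specification.

    The specification is a plain mapping with keys ``proteins`` (protein ->
    ordered state list), ``reactions`` (list of mappings with substrate,
    product, rate and optional modifier), ``outputs`` and optionally
    ``initial_pool`` and default ``rates``. ``kpar`` overrides the
    specification's rates.

    When ``verify_inactive`` is set the model is integrated at signal 0 and
    required to stay fully unphosphorylated — the stable inactive state every
    admissible cascade must possess.
    """
    rates = dict(topology.get("rates") or {})
    if kpar is not None:
        rates.update(kpar)
    reactions = tuple(
        Reaction(
            substrate=r["substrate"],
            product=r["product"],
            rate=r["rate"],
            modifier=r.get("modifier"),
        )
        for r in topology["reactions"]
    )
    missing = {r.rate for r in reactions} - set(rates)
    if missing:
        raise TopologyError(f"no rate values supplied for {sorted(missing)}")
    model = CascadeModel(
        proteins={p: tuple(states) for p, states in topology["proteins"].items()},
        reactions=reactions,
        kpar=rates,
        outputs=tuple(topology["outputs"]),
        pool=float(topology.get("initial_pool", DEFAULT_POOL)),
    )
    if verify_inactive:
        traj = simulate(model, signal=0.0)
        phospho = traj.y.copy()
        for states in model.proteins.values():
            phospho[:, model._index[states[0]]] = 0.0
        if np.max(phospho) > 1e-6 * model.pool:
            raise TopologyError("cascade has no stable inactive state at signal 0")
    return model


def load_topology(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_topology(topology: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(topology, fh, sort_keys=False)


def _cascade_reactions(prefix: str = "") -> list[dict]:
    """Receptor -> kinase -> target ladder driven by the external signal."""
    p = prefix
    ladder = []
    # receptor level: both phosphorylations driven by the signal
    ladder += [
        {"substrate": f"{p}R0", "product": f"{p}R1", "modifier": SIGNAL_MODIFIER, "rate": f"{p}k_aR1"},
        {"substrate": f"{p}R1", "product": f"{p}R2", "modifier": SIGNAL_MODIFIER, "rate": f"{p}k_aR2"},
        {"substrate": f"{p}R2", "product": f"{p}R1", "rate": f"{p}k_dR2"},
        {"substrate": f"{p}R1", "product": f"{p}R0", "rate": f"{p}k_dR1"},
    ]
    # intracellular level: catalysed by dual-phosphorylated receptor
    ladder += [
        {"substrate": f"{p}K0", "product": f"{p}K1", "modifier": f"{p}R2", "rate": f"{p}k_aK1"},
        {"substrate": f"{p}K1", "product": f"{p}K2", "modifier": f"{p}R2", "rate": f"{p}k_aK2"},
        {"substrate": f"{p}K2", "product": f"{p}K1", "rate": f"{p}k_dK2"},
        {"substrate": f"{p}K1", "product": f"{p}K0", "rate": f"{p}k_dK1"},
    ]
    # target level: catalysed by dual-phosphorylated kinase
    ladder += [
        {"substrate": f"{p}T0", "product": f"{p}T1", "modifier": f"{p}K2", "rate": f"{p}k_aT1"},
        {"substrate": f"{p}T1", "product": f"{p}T2", "modifier": f"{p}K2", "rate": f"{p}k_aT2"},
        {"substrate": f"{p}T2", "product": f"{p}T1", "rate": f"{p}k_dT2"},
        {"substrate": f"{p}T1", "product": f"{p}T0", "rate": f"{p}k_dT1"},
    ]
    return ladder


def _cascade_proteins(prefix: str = "") -> dict[str, list[str]]:
    p = prefix
    return {
        f"{p}R": [f"{p}R0", f"{p}R1", f"{p}R2"],
        f"{p}K": [f"{p}K0", f"{p}K1", f"{p}K2"],
        f"{p}T": [f"{p}T0", f"{p}T1", f"{p}T2"],
    }


def three_level_topology(
    n_cascades: int = 1,
    feedback: list[dict] | None = None,
    feedforward: list[dict] | None = None,
    crosstalk: list[dict] | None = None,
    rates: dict[str, float] | None = None,
    initial_pool: float = DEFAULT_POOL,
) -> dict:
    """Assemble a topology spec for one or two three-level cascades.

    ``feedback``/``feedforward``/``crosstalk`` entries are reaction mappings
    (substrate, product, modifier, rate) appended to the ladder; a negative
    feedback loop is a phospho-form-catalysed dephosphorylation of an
    upstream species, a feedforward loop an extra catalysed phosphorylation,
    and a crosstalk edge a reaction of one cascade modified by an active
    species of the other.
    """
    if n_cascades not in (1, 2):
        raise TopologyError("only 1 or 2 cascades are supported")
    prefixes = [""] if n_cascades == 1 else ["C1_", "C2_"]
    proteins: dict[str, list[str]] = {}
    reactions: list[dict] = []
    for p in prefixes:
        proteins.update(_cascade_proteins(p))
        reactions += _cascade_reactions(p)
    reactions += list(feedback or []) + list(feedforward or []) + list(crosstalk or [])
    outputs = [f"{p}T2" for p in prefixes]
    topo: dict = {
        "proteins": proteins,
        "reactions": reactions,
        "outputs": outputs,
        "initial_pool": initial_pool,
    }
    if rates is not None:
        topo["rates"] = dict(rates)
    return topo


def plain_topology(rates: dict[str, float] | None = None) -> dict:
    """Single three-level cascade without loops."""
    return three_level_topology(1, rates=rates)


def fit_example_rates(topology: dict, prefix: str = "") -> dict[str, float]:
    """Rates that make a ladder provably responsive for every input signal.

    Signal-driven receptor steps get a large constant so that even the
    weakest signal (1e-4) activates within the fitness horizon; kinase-
    catalysed steps are strong and dephosphorylation weak, so the
    dual-phosphorylated target rises far above the 1/10 threshold.
    Restricted to rates with the given prefix when two cascades coexist.
    """
    rates: dict[str, float] = {}
    for r in topology["reactions"]:
        rid = r["rate"]
        if prefix and not rid.startswith(prefix):
            continue
        if r.get("modifier") == SIGNAL_MODIFIER:
            rates[rid] = 2000.0
        elif r.get("modifier"):
            rates[rid] = 5.0
        else:
            rates[rid] = 0.1
    return rates


def _uniform_rates(topology: dict, value: float) -> dict[str, float]:
    return {r["rate"]: value for r in topology["reactions"]}


def _ladder_rates(topo: dict, k_aR: float = 200.0, k_a: float = 2.0, k_d: float = 0.2) -> dict:
    rates = {}
    for r in topo["reactions"]:
        rid = r["rate"]
        if rid.startswith("k_aR"):
            rates[rid] = k_aR       # signal-driven; keeps S=1e-4 responsive
        elif rid.startswith("k_a"):
            rates[rid] = k_a
        elif rid.startswith("k_d"):
            rates[rid] = k_d
    return rates


def normal_topology() -> dict:
    """Shipped example: cascade with negative feedback via an induced inhibitor.

    The dual-phosphorylated target slowly activates an inhibitor protein P
    (after the fashion of ppERK-induced DUSP phosphatases) whose active form
    dephosphorylates the receptor and kinase levels. The induction delay lets
    ppTP overshoot before the accumulated inhibitor clamps the cascade to a
    low steady state, so the response is transient across the whole
    signal range.
    """
    topo = three_level_topology(1)
    topo["proteins"]["P"] = ["P0", "P1"]
    topo["reactions"] += [
        {"substrate": "P0", "product": "P1", "modifier": "T2", "rate": "k_pa"},
        {"substrate": "P1", "product": "P0", "rate": "k_pd"},
        {"substrate": "K2", "product": "K1", "modifier": "P1", "rate": "k_fbl"},
        {"substrate": "K1", "product": "K0", "modifier": "P1", "rate": "k_fbl"},
        {"substrate": "R2", "product": "R1", "modifier": "P1", "rate": "k_fbl"},
        {"substrate": "R1", "product": "R0", "modifier": "P1", "rate": "k_fbl"},
    ]
    rates = _ladder_rates(topo)
    rates.update(k_pa=0.05, k_pd=0.01, k_fbl=50.0)
    topo["rates"] = rates
    return topo


def cancer_topology() -> dict:
    """Shipped example: the same cascade with the feedback loop deleted.

    Without the inhibitor the ladder is a monotone relay and ppTP rises to a
    sustained plateau at every signal strength — the lesion modelling
    constitutively active signaling.
    """
    topo = three_level_topology(1)
    topo["rates"] = _ladder_rates(topo)
    return topo


def crosstalk_topology(rates: dict[str, float] | None = None) -> dict:
    """Two cascades with one activating crosstalk edge (C1 kinase -> C2 kinase)."""
    topo = three_level_topology(
        2,
        crosstalk=[
            {
                "substrate": "C2_K0",
                "product": "C2_K1",
                "modifier": "C1_K2",
                "rate": "k_ct",
            }
        ],
        rates=rates,
    )
    return topo


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    t: np.ndarray
    y: np.ndarray               # n_points x n_species
    species: tuple[str, ...]
    signal: float

    def of(self, species: str) -> np.ndarray:
        return self.y[:, self.species.index(species)]


class SimulationError(RuntimeError):
    def __init__(self, message: str, kpar: dict | None = None, signal: float | None = None):
        super().__init__(message)
        self.kpar = kpar
        self.signal = signal


def _rhs_single(comp: _Compiled, k_eff: np.ndarray):
    """Right-hand side closure for one model; k_eff already includes the signal."""
    sub, mod_idx, is_spec, stoich = comp.sub, comp.mod_idx, comp.mod_is_species, comp.stoich

    def rhs(x, t):
        rates = k_eff * x[sub]
        rates[is_spec] *= x[mod_idx[is_spec]]
        return stoich @ rates

    return rhs


def _effective_k(comp: _Compiled, kvec: np.ndarray, signal: float) -> np.ndarray:
    k = comp.rate_constants(kvec).astype(float).copy()
    k[..., comp.mod_is_signal] *= signal
    return k


def simulate(
    model: CascadeModel,
    signal: float,
    t_end: float = 100.0,
    n_points: int = 500,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the mass-action ODEs on a fixed output grid (LSODA)."""
    if signal < 0:
        raise ValueError("signal must be >= 0")
    comp = model.compiled()
    k_eff = _effective_k(comp, model.kpar_vector(), signal)
    t = np.linspace(0.0, t_end, n_points)
    y, info = odeint(
        _rhs_single(comp, k_eff), comp.x0, t,
        rtol=rtol, atol=atol, full_output=True, mxstep=100000,
    )
    if info["message"] != "Integration successful.":
        raise SimulationError(
            f"ODE integration failed: {info['message']}",
            kpar=dict(model.kpar), signal=signal,
        )
    return Trajectory(t=t, y=y, species=model.species, signal=signal)


def check_conservation(model: CascadeModel, traj: Trajectory, rtol: float = 1e-6) -> None:
    """Raise if any protein total drifts by more than ``rtol`` relative."""
    for protein, totals in model.protein_totals(traj.y).items():
        drift = np.max(np.abs(totals - model.pool)) / model.pool
        if drift > rtol:
            raise SimulationError(
                f"protein {protein} total drifted by {drift:.2e} relative"
            )


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

@dataclass
class FitnessSpec:
    """Evaluation protocol for the six-signal fitness test."""

    signals: tuple[float, ...] = SIGNALS
    threshold_fraction: float = THRESHOLD_FRACTION
    t_end: float = 100.0
    n_points: int = 500
    rtol: float = 1e-6
    atol: float = 1e-9


@dataclass
class FitnessResult:
    F: float
    ffactor1: np.ndarray        # per signal
    ffactor2: np.ndarray        # per signal; all zero in single-cascade mode
    signals: tuple[float, ...]


def _factors_from_crossings(crossed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map per-(cascade, signal) threshold crossings to fitness factors.

    ``crossed`` has shape (n_outputs, n_signals). A lone cascade scores 1.0
    per responsive signal; in crosstalk mode each responsive cascade scores
    0.5 (cascade 1 -> Ffactor1, cascade 2 -> Ffactor2).
    """
    n_out, n_sig = crossed.shape
    f1 = np.zeros(n_sig)
    f2 = np.zeros(n_sig)
    if n_out == 1:
        f1[crossed[0]] = 1.0
    elif n_out == 2:
        f1[crossed[0]] = 0.5
        f2[crossed[1]] = 0.5
    else:  # pragma: no cover - topology builders only emit 1 or 2 outputs
        raise ValueError("fitness is defined for 1 or 2 cascades")
    return f1, f2


def fitness(model: CascadeModel, spec: FitnessSpec | None = None) -> FitnessResult:
    """Six-signal fitness of one cascade model (Ffactor rules above)."""
    spec = spec or FitnessSpec()
    comp = model.compiled()
    threshold = spec.threshold_fraction * model.pool
    crossed = np.zeros((len(comp.out_idx), len(spec.signals)), dtype=bool)
    for j, s in enumerate(spec.signals):
        traj = simulate(model, s, spec.t_end, spec.n_points, spec.rtol, spec.atol)
        peak = traj.y[:, comp.out_idx].max(axis=0)
        crossed[:, j] = peak > threshold
    f1, f2 = _factors_from_crossings(crossed)
    F = (f1.sum() + f2.sum()) / len(spec.signals)
    return FitnessResult(F=float(F), ffactor1=f1, ffactor2=f2, signals=spec.signals)


def _population_rhs(comp: _Compiled, K_eff: np.ndarray, n_species: int):
    """RHS for a whole population stacked into one block-diagonal system."""
    sub, mod_idx, is_spec = comp.sub, comp.mod_idx, comp.mod_is_species
    stoichT = comp.stoich.T  # n_reactions x n_species
    P = K_eff.shape[0]

    def rhs(x_flat, t):
        X = x_flat.reshape(P, n_species)
        rates = K_eff * X[:, sub]
        rates[:, is_spec] *= X[:, mod_idx[is_spec]]
        return (rates @ stoichT).ravel()

    return rhs


def _population_peaks(
    comp: _Compiled,
    K: np.ndarray,
    signal: float,
    spec: FitnessSpec,
    n_species: int,
) -> np.ndarray:
    """Peak output concentrations, shape (P, n_outputs), for one signal.

    The whole population is integrated as one block-diagonal ODE system —
    trajectories agree with per-model integration to within the shared
    integrator tolerance.
    """
    P = K.shape[0]
    K_eff = comp.rate_constants(K).astype(float)
    K_eff[:, comp.mod_is_signal] *= signal
    x0 = np.tile(comp.x0, P)
    t = np.linspace(0.0, spec.t_end, spec.n_points)
    y, info = odeint(
        _population_rhs(comp, K_eff, n_species), x0, t,
        rtol=spec.rtol, atol=spec.atol, full_output=True, mxstep=100000,
    )
    if info["message"] != "Integration successful.":
        raise SimulationError(f"population integration failed: {info['message']}")
    Y = y.reshape(spec.n_points, P, n_species)
    return Y[:, :, comp.out_idx].max(axis=0)


def population_fitness(
    template: CascadeModel, K: np.ndarray, spec: FitnessSpec | None = None
) -> np.ndarray:
    """Fitness F for every kpar row of ``K`` (population x n_rates)."""
    spec = spec or FitnessSpec()
    comp = template.compiled()
    threshold = spec.threshold_fraction * template.pool
    P = K.shape[0]
    n_out = len(comp.out_idx)
    crossed = np.zeros((P, n_out, len(spec.signals)), dtype=bool)
    for j, s in enumerate(spec.signals):
        peaks = _population_peaks(comp, K, s, spec, template.n_species)
        crossed[:, :, j] = peaks > threshold
    F = np.empty(P)
    for i in range(P):
        f1, f2 = _factors_from_crossings(crossed[i])
        F[i] = (f1.sum() + f2.sum()) / len(spec.signals)
    return F


# ---------------------------------------------------------------------------
# evolutionary optimisation
# ---------------------------------------------------------------------------

@dataclass
class EvolutionConfig:
    """Population-level settings for the evolutionary search."""

    population: int = 200
    survivors: int = 50
    copies_per_survivor: int = 4
    generations: int = 200
    kpar_init_range: tuple[float, float] = (0.001, 0.1)
    kpar_bounds: tuple[float, float] = (0.01, 100.0)
    mutation_prob: float = 0.5
    mutation_factor_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.survivors * self.copies_per_survivor != self.population:
            raise ValueError("survivors * copies_per_survivor must equal population")


@dataclass
class EvolutionRun:
    best_model: CascadeModel
    best_F: float
    best_per_generation: np.ndarray     # length generations + 1
    mean_per_generation: np.ndarray
    config: EvolutionConfig
    final_population: np.ndarray        # population x n_rates
    final_fitness: np.ndarray


def _mutate(K: np.ndarray, cfg: EvolutionConfig, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative jitter: each rate x U[0.5, 2] with prob 0.5, clipped."""
    factors = rng.uniform(*cfg.mutation_factor_range, size=K.shape)
    mask = rng.random(K.shape) < cfg.mutation_prob
    out = np.where(mask, K * factors, K)
    return np.clip(out, *cfg.kpar_bounds)


def evolve(
    topology: dict,
    config: EvolutionConfig | None = None,
    fitness_spec: FitnessSpec | None = None,
) -> EvolutionRun:
    """Evolve kinetic parameters of a fixed topology to maximise fitness.

    Each generation keeps the best ``survivors`` cascades and replaces the
    population with ``copies_per_survivor`` copies of each: one elite copy
    with unchanged rates (whose cached fitness is carried over, making the
    best fitness non-decreasing by construction) and the rest mutated.
    Fully reproducible from ``config.seed``.
    """
    cfg = config or EvolutionConfig()
    spec = fitness_spec or FitnessSpec()
    rng = np.random.default_rng(cfg.seed)
    placeholder = {rid: 1.0 for rid in _topology_rate_ids(topology)}
    template = build_cascade(topology, kpar=placeholder, verify_inactive=True)
    n_rates = len(template.rate_ids)

    K = rng.uniform(*cfg.kpar_init_range, size=(cfg.population, n_rates))
    F = population_fitness(template, K, spec)
    best_hist = [F.max()]
    mean_hist = [F.mean()]

    for _ in range(cfg.generations):
        order = np.argsort(-F, kind="stable")[: cfg.survivors]
        parents = K[order]
        parent_F = F[order]
        # one elite copy per survivor plus (copies - 1) mutated copies;
        # mutants are interleaved one-per-parent so that on fitness ties the
        # index-ordered selection keeps one offspring of every lineage
        # rather than flooding the survivor slots with a single parent's
        K_elite = parents.copy()
        fresh = []
        for _c in range(cfg.copies_per_survivor - 1):
            for i in range(cfg.survivors):
                fresh.append(_mutate(parents[i][None, :], cfg, rng))
        K_fresh = np.vstack(fresh)
        F_fresh = population_fitness(template, K_fresh, spec)
        # mutated copies take the low indices: on fitness ties the stable
        # index-ordered selection then prefers them over their elite parents,
        # which lets rates drift across fitness plateaus while the elite
        # copies still guarantee a non-decreasing best fitness
        K = np.vstack([K_fresh, K_elite])
        F = np.concatenate([F_fresh, parent_F])
        best_hist.append(F.max())
        mean_hist.append(F.mean())

    best_i = int(np.argsort(-F, kind="stable")[0])
    best_kpar = dict(zip(template.rate_ids, K[best_i]))
    return EvolutionRun(
        best_model=template.with_kpar(best_kpar),
        best_F=float(F[best_i]),
        best_per_generation=np.array(best_hist),
        mean_per_generation=np.array(mean_hist),
        config=cfg,
        final_population=K,
        final_fitness=F,
    )


def _topology_rate_ids(topology: dict) -> list[str]:
    seen: dict[str, None] = {}
    for r in topology["reactions"]:
        seen.setdefault(r["rate"], None)
    return list(seen)


# ---------------------------------------------------------------------------
# normal-vs-lesion kinetics comparison
# ---------------------------------------------------------------------------

TRANSIENT = "transient"
SUSTAINED = "sustained"
NO_RESPONSE = "none"


def classify_response(
    traj_out: np.ndarray,
    pool: float = DEFAULT_POOL,
    decline_fraction: float = 0.5,
    activity_floor: float = 1e-9,
) -> str:
    """Label an output time course as transient, sustained, or no response.

    Transient means the trajectory peaks and then falls below
    ``decline_fraction`` of its peak by the end of the horizon; sustained
    means it stays at or above that fraction. A trace whose peak never
    exceeds ``activity_floor * pool`` is unlabelled ("none").
    """
    peak = float(np.max(traj_out))
    if peak <= activity_floor * pool:
        return NO_RESPONSE
    return TRANSIENT if traj_out[-1] < decline_fraction * peak else SUSTAINED


def compare_normal_vs_cancer(
    base: CascadeModel,
    perturbed: CascadeModel,
    signals: tuple[float, ...] = SIGNALS,
    t_end: float = 2000.0,
    n_points: int = 2000,
) -> dict:
    """Classify ppTP kinetics of a feedback-intact vs a feedback-lesioned model.

    The horizon is long relative to the fitness evaluation so that responses
    to the weakest signals have time to complete their transient.
    """
    report: dict = {"signals": list(signals), "base": {}, "perturbed": {}}
    for label, model in (("base", base), ("perturbed", perturbed)):
        out_species = model.outputs[0]
        for s in signals:
            traj = simulate(model, s, t_end=t_end, n_points=n_points)
            report[label][s] = classify_response(traj.of(out_species), model.pool)
    return report
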