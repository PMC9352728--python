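"""Ensemble-averaged distance restraints and two-state rigid-body fitting.

A multi-state ensemble must satisfy time- and ensemble-averaged probes
through the average of the back-calculated contributions of each state,
not through each state alone: NOE and PRE distances average as
population-weighted <r^-6>^(-1/6), DEER effective distances (already
population averages by construction) average linearly. An ensemble is
scored by a target function TF = sum_i w_i * violation_i^2 (A^2) with
flat-bottom violations (zero inside [lower, upper], linear distance
outside, squared in the sum). Default weights: NOE 1, DEER 1, PRE 0.01.

The structure generator here is a deliberate rigid-body surrogate for a
full torsion-angle annealing engine: domain A is fixed, domain B is
placed per state with 6 rigid degrees of freedom, and state populations
are either optimized in [0.05, 0.95] or fixed from an upstream DEER
fit. This is sufficient to expose the central inference — that compact-
only contacts and extended-state distances cannot be satisfied by any
single placement, while a two-state ensemble satisfies both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .forward import DistanceDistribution

__all__ = [
    "AtomKey",
    "Conformer",
    "RigidDomain",
    "DistanceRestraint",
    "TwoStateEnsemble",
    "TargetFunctionReport",
    "effective_deer_distance",
    "make_limits",
    "ensemble_average_distance",
    "target_function",
    "optimize_two_state",
    "karplus_backcalc",
    "KARPLUS_COEFFICIENTS",
    "DEFAULT_WEIGHTS",
]

AtomKey = tuple[int, str]

DEFAULT_WEIGHTS = {"NOE": 1.0, "DEER": 1.0, "PRE": 0.01}
_DEFAULT_AVERAGING = {"NOE": "r6", "PRE": "r6", "DEER": "linear"}


@dataclass
class Conformer:
    """One coordinate set: (residue, atom name) -> xyz in Angstrom."""

    coords: dict[AtomKey, np.ndarray]
    res_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = {k: np.asarray(v, dtype=float) for k, v in self.coords.items()}

    def position(self, atom: AtomKey) -> np.ndarray:
        try:
            return self.coords[atom]
        except KeyError:
            raise KeyError(f"atom {atom[1]} of residue {atom[0]} not in conformer") from None

    def res_name(self, residue: int) -> str:
        return self.res_names.get(residue, "ALA")

    def transformed(self, rotation: Rotation, translation: np.ndarray) -> "Conformer":
        keys = list(self.coords)
        xyz = rotation.apply(np.array([self.coords[k] for k in keys])) + translation
        return Conformer(dict(zip(keys, xyz)), dict(self.res_names))

    def merged(self, other: "Conformer") -> "Conformer":
        coords = dict(self.coords)
        coords.update(other.coords)
        names = dict(self.res_names)
        names.update(other.res_names)
        return Conformer(coords, names)


@dataclass
class RigidDomain:
    """A rigid coordinate body (one protein domain) used for placement."""

    conformer: Conformer

    @property
    def center(self) -> np.ndarray:
        return np.mean(list(self.conformer.coords.values()), axis=0)


@dataclass(frozen=True)
class DistanceRestraint:
    """Distance bound between two atoms with kind-specific averaging.

    ``state`` restricts the restraint to one state's back-calculated
    distance (1-based); ``None`` means the restraint applies to the
    ensemble average, which is the default and the experimentally
    faithful mode.
    """

    atom_a: AtomKey
    atom_b: AtomKey
    kind: str
    lower: float
    upper: float
    weight: float | None = None
    averaging: str | None = None
    state: int | None = None
    res_name_a: str = "ALA"
    res_name_b: str = "ALA"

    def __post_init__(self) -> None:
        if self.kind not in DEFAULT_WEIGHTS:
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")
        if self.weight is None:
            object.__setattr__(self, "weight", DEFAULT_WEIGHTS[self.kind])
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.averaging is None:
            object.__setattr__(self, "averaging", _DEFAULT_AVERAGING[self.kind])
        if self.averaging not in ("r6", "linear"):
            raise ValueError(f"unknown averaging mode {self.averaging!r}")

    def pair_id(self) -> tuple:
        """Order-normalized identity used for restraint-set overlap."""
        a, b = sorted((self.atom_a, self.atom_b))
        return (a, b, self.kind)


@dataclass
class TwoStateEnsemble:
    """Conformers partitioned into one or two states with populations."""

    conformers: list[Conformer]
    state_labels: list[int]
    populations: np.ndarray

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=float)
        if len(self.conformers) != len(self.state_labels):
            raise ValueError("every conformer needs a state label")
        states = sorted(set(self.state_labels))
        if states not in ([1], [2], [1, 2]):
            raise ValueError("states must be labeled 1 and/or 2")
        if len(self.populations) != len(states):
            raise ValueError("one population per state required")
        if abs(self.populations.sum() - 1.0) > 1e-9:
            raise ValueError("populations must sum to 1")

    @property
    def states(self) -> list[int]:
        return sorted(set(self.state_labels))

    def state_conformers(self, state: int) -> list[Conformer]:
        return [c for c, s in zip(self.conformers, self.state_labels) if s == state]

    def population_of(self, state: int) -> float:
        return float(self.populations[self.states.index(state)])


@dataclass
class TargetFunctionReport:
    """Restraint-violation summary; tf = sum of weight * violation^2 (A^2)."""

    tf: float
    per_restraint: list[dict]
    n_violated: int

    def summary(self) -> dict:
        return {"tf_A2": self.tf, "n_restraints": len(self.per_restraint),
                "n_violated": self.n_violated}


def effective_deer_distance(dist: DistanceDistribution) -> float:
    """Population- and fluctuation-averaged distance <r> = int r P(r) dr."""
    z = dist.integral()
    if abs(z - 1.0) > 1e-6:
        warnings.warn("distribution was not normalized; normalizing", stacklevel=2)
        dist = dist.normalized()
    return dist.mean()


def make_limits(distance: float, tolerance: float = 5.0) -> tuple[float, float]:
    """Effective distance -> (lower, upper) = distance -/+ tolerance.

    The lower limit is clamped at 1 A (with a warning) when the
    tolerance exceeds the distance.
    """
    lower = distance - tolerance
    if lower < 1.0:
        warnings.warn(
            f"lower limit {lower:.2f} A clamped to 1 A", stacklevel=2)
        lower = 1.0
    return (lower, distance + tolerance)


def _state_distance(ensemble: TwoStateEnsemble, state: int, pair: tuple[AtomKey, AtomKey]) -> float:
    confs = ensemble.state_conformers(state)
    d = [float(np.linalg.norm(c.position(pair[0]) - c.position(pair[1]))) for c in confs]
    return float(np.mean(d))


def ensemble_average_distance(
    ensemble: TwoStateEnsemble,
    pair: tuple[AtomKey, AtomKey],
    averaging: str = "r6",
) -> float:
    """Population-averaged effective distance over the states.

    "r6":     r_eff = (sum_s pop_s r_s^-6)^(-1/6)  (NOE/PRE physics)
    "linear": r_eff = sum_s pop_s r_s              (DEER effective distances)

    with r_s the mean distance over the conformers of state s.
    """
    pops = [ensemble.population_of(s) for s in ensemble.states]
    dists = np.array([_state_distance(ensemble, s, pair) for s in ensemble.states])
    pops = np.asarray(pops)
    if averaging == "r6":
        return float(np.sum(pops * dists**-6.0) ** (-1.0 / 6.0))
    if averaging == "linear":
        return float(np.sum(pops * dists))
    raise ValueError(f"unknown averaging mode {averaging!r}")


def _restraint_distance(ensemble: TwoStateEnsemble, restraint: DistanceRestraint) -> float:
    pair = (restraint.atom_a, restraint.atom_b)
    if restraint.state is not None:
        state = restraint.state if restraint.state in ensemble.states else ensemble.states[-1]
        return _state_distance(ensemble, state, pair)
    return ensemble_average_distance(ensemble, pair, restraint.averaging)


def target_function(
    ensemble: TwoStateEnsemble,
    restraints: list[DistanceRestraint],
    violation_cutoff: float = 1e-6,
) -> TargetFunctionReport:
    """Score an ensemble: TF = sum_i w_i * violation_i^2 over all restraints."""
    if not restraints:
        warnings.warn("empty restraint list; TF = 0", stacklevel=2)
        return TargetFunctionReport(0.0, [], 0)
    rows = []
    tf = 0.0
    n_violated = 0
    for res in restraints:
        r_eff = _restraint_distance(ensemble, res)
        violation = max(0.0, r_eff - res.upper) + max(0.0, res.lower - r_eff)
        contrib = res.weight * violation**2
        tf += contrib
        if violation > violation_cutoff:
            n_violated += 1
        rows.append({
            "atom_a": res.atom_a, "atom_b": res.atom_b, "kind": res.kind,
            "r_eff_A": r_eff, "lower_A": res.lower, "upper_A": res.upper,
            "violation_A": violation, "weighted_sq_A2": contrib,
        })
    return TargetFunctionReport(tf, rows, n_violated)


def _locate(restraints: list[DistanceRestraint], a: Conformer, b: Conformer) -> list[tuple]:
    """For each restraint find which domain each atom belongs to."""
    located = []
    any_interdomain = False
    for res in restraints:
        spots = []
        for atom in (res.atom_a, res.atom_b):
            if atom in a.coords:
                spots.append(("A", atom))
            elif atom in b.coords:
                spots.append(("B", atom))
            else:
                raise KeyError(f"restraint atom {atom} found in neither domain")
        if {spots[0][0], spots[1][0]} == {"A", "B"}:
            any_interdomain = True
        located.append(tuple(spots))
    if not any_interdomain:
        raise ValueError("no interdomain restraints; domain placement is unconstrained")
    return located


def _build_ensemble(domain_a: Conformer, domain_b: Conformer, x: np.ndarray,
                    n_states: int, populations: np.ndarray | None) -> TwoStateEnsemble:
    confs = []
    for s in range(n_states):
        rv = x[6 * s : 6 * s + 3]
        t = x[6 * s + 3 : 6 * s + 6]
        b = domain_b.transformed(Rotation.from_rotvec(rv), t)
        confs.append(domain_a.merged(b))
    if populations is None:
        p1 = x[6 * n_states] if n_states == 2 else 1.0
        pops = np.array([p1, 1.0 - p1]) if n_states == 2 else np.array([1.0])
    else:
        pops = populations
    return TwoStateEnsemble(confs, list(range(1, n_states + 1)), pops)


def optimize_two_state(
    domain_a: "Conformer | RigidDomain",
    domain_b: "Conformer | RigidDomain",
    restraints: list[DistanceRestraint],
    n_states: int = 2,
    n_starts: int = 8,
    seed: int | None = 0,
    populations: "np.ndarray | tuple | None" = None,
) -> tuple[TwoStateEnsemble, TargetFunctionReport]:
    """Place rigid domain B relative to fixed domain A to satisfy restraints.

    Optimizes 6 rigid-body degrees of freedom per state (rotation vector
    plus translation) and, unless ``populations`` is given, the state-1
    population within [0.05, 0.95], by seeded multi-start trust-region
    least squares on sqrt(weight) * violation residuals. Deterministic
    given ``seed``; returns the best ensemble with its TF report.
    """
    if n_states not in (1, 2):
        raise ValueError("n_states must be 1 or 2")
    a = domain_a.conformer if isinstance(domain_a, RigidDomain) else domain_a
    b = domain_b.conformer if isinstance(domain_b, RigidDomain) else domain_b
    located = _locate(restraints, a, b)  # validates atoms + interdomain coverage
    if populations is not None:
        populations = np.asarray(populations, dtype=float)[:n_states]
        populations = populations / populations.sum()
    rng = np.random.default_rng(seed)

    n_dof = 6 * n_states + (1 if (n_states == 2 and populations is None) else 0)
    lo = np.concatenate([np.tile([-2 * np.pi] * 3 + [-100.0] * 3, n_states),
                         [0.05] if n_dof > 6 * n_states else []])
    hi = np.concatenate([np.tile([2 * np.pi] * 3 + [100.0] * 3, n_states),
                         [0.95] if n_dof > 6 * n_states else []])

    # flatten restraint atoms into fixed (domain A) and mobile (domain B) arrays
    n_res = len(restraints)
    b_index: dict[AtomKey, int] = {}
    a_store: list[np.ndarray] = []
    sides = np.empty((n_res, 2), dtype=bool)  # True = domain A (fixed)
    idx = np.empty((n_res, 2), dtype=int)

    def _slot(side: str, atom: AtomKey) -> int:
        if side == "A":
            a_store.append(a.coords[atom])
            return len(a_store) - 1
        if atom not in b_index:
            b_index[atom] = len(b_index)
        return b_index[atom]

    for i, pair in enumerate(located):
        for j, (side, atom) in enumerate(pair):
            sides[i, j] = side == "A"
            idx[i, j] = _slot(side, atom)
    a_arr = np.array(a_store) if a_store else np.zeros((0, 3))
    b_arr = np.array([b.coords[k] for k in b_index]) if b_index else np.zeros((0, 3))

    lowers = np.array([r.lower for r in restraints])
    uppers = np.array([r.upper for r in restraints])
    sqrt_w = np.sqrt(np.array([r.weight for r in restraints]))
    is_r6 = np.array([r.averaging == "r6" and r.state is None for r in restraints])
    is_lin = np.array([r.averaging == "linear" and r.state is None for r in restraints])
    state_sel = np.array([
        0 if r.state is None else np.clip(r.state, 1, n_states) for r in restraints
    ])

    def _state_dists(x_s: np.ndarray) -> np.ndarray:
        bt = Rotation.from_rotvec(x_s[:3]).apply(b_arr) + x_s[3:6] if len(b_arr) else b_arr
        pts = np.empty((n_res, 2, 3))
        for j in range(2):
            m = sides[:, j]
            pts[m, j] = a_arr[idx[m, j]]
            pts[~m, j] = bt[idx[~m, j]]
        return np.linalg.norm(pts[:, 0] - pts[:, 1], axis=1)

    def residuals(x: np.ndarray) -> np.ndarray:
        d_states = np.stack([_state_dists(x[6 * s : 6 * s + 6]) for s in range(n_states)])
        if n_states == 1:
            pops = np.array([1.0])
        elif populations is None:
            pops = np.array([x[-1], 1.0 - x[-1]])
        else:
            pops = populations
        r6 = (pops[:, None] * d_states**-6.0).sum(axis=0) ** (-1.0 / 6.0)
        lin = (pops[:, None] * d_states).sum(axis=0)
        picked = d_states[np.clip(state_sel - 1, 0, n_states - 1), np.arange(n_res)]
        r_eff = np.where(is_r6, r6, np.where(is_lin, lin, picked))
        viol = np.maximum(0.0, r_eff - uppers) + np.maximum(0.0, lowers - r_eff)
        return sqrt_w * viol

    best_x, best_cost = None, np.inf
    for start in range(max(1, n_starts)):
        x0 = np.empty(n_dof)
        for s in range(n_states):
            x0[6 * s : 6 * s + 3] = rng.uniform(-np.pi, np.pi, 3)
            x0[6 * s + 3 : 6 * s + 6] = rng.uniform(-40.0, 40.0, 3)
        if n_dof > 6 * n_states:
            x0[-1] = 0.5
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            diff_step=1e-4)
        if sol.cost < best_cost:
            best_x, best_cost = sol.x, sol.cost
        if best_cost < 1e-12:
            break
    ens = _build_ensemble(a, b, best_x, n_states, populations)
    return ens, target_function(ens, restraints)


#: Karplus coefficients (A, B, C) in Hz and phase offset (deg) applied as
#: J = A cos^2(theta + offset) + B cos(theta + offset) + C. Standard
#: parameterizations for backbone/side-chain couplings.
KARPLUS_COEFFICIENTS: dict[str, tuple[float, float, float, float]] = {
    "3JHNHA": (7.09, -1.42, 1.55, -60.0),   # vs phi
    "3JHAHB": (9.50, -1.60, 1.80, -120.0),  # vs chi1
    "3JNCG": (1.29, -0.49, 0.37, 0.0),      # vs chi1
}


def karplus_backcalc(dihedral_deg: "float | np.ndarray", coupling_type: str) -> "float | np.ndarray":
    """Back-calculate a three-bond scalar coupling from a dihedral angle."""
    try:
        a, b, c, offset = KARPLUS_COEFFICIENTS[coupling_type]
    except KeyError:
        raise ValueError(
            f"no Karplus coefficients registered for {coupling_type!r}; "
            f"known types: {sorted(KARPLUS_COEFFICIENTS)}") from None
    theta = np.deg2rad(np.asarray(dihedral_deg, dtype=float) + offset)
    j = a * np.cos(theta) ** 2 + b * np.cos(theta) + c
    if j.ndim == 0:
        return float(j)
    return j
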