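"""Population-metaheuristic wrapper feature selection.

Seven selectors search over binary feature masks by moving a population of
continuous positions inside a box, binarizing each position with a sigmoid
transfer thresholded at 0.5 (equivalently, coordinate > 0), and scoring the
resulting mask with a cross-validated wrapper fitness:

    fitness(mask) = (1/S) * sum_s (N_s - E_s) / N_s * 100

over S stratified inner folds, where E_s is the misclassification count of a
cheap base classifier (5-nearest-neighbors by default) trained on the masked
training portion. Fitness is cached per mask, empty masks are repaired to the
single feature with the highest point-biserial |correlation| to the labels,
and every selector keeps an elitist best-so-far whose fitness trace is
monotone non-decreasing.

Selectors
---------
cso        cuckoo search (Levy-flight proposals, abandonment walk)
rso        rat swarm (best-guided linear-decay update)
cso_rso    hybrid: both proposals per agent each iteration, greedy keep
zoa        zebra optimization (foraging toward the pioneer + defense phases)
gsa        gravitational search (mass-weighted attraction, decaying constant)
pso        particle swarm (inertia + cognitive + social velocity)
gsa_pso    hybrid: GSA acceleration in PSO's cognitive slot + gbest attraction
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .data import LabeledDataset, ValidationError

BOUNDS = (-5.0, 5.0)     # symmetric around the sigmoid switch point


# ---------------------------------------------------------------------------
# binarization and fitness
# ---------------------------------------------------------------------------

def repair_feature(X: np.ndarray, y: np.ndarray) -> int:
    """Index of the feature with highest point-biserial |correlation| to y."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(Xc.T @ yc) / np.where(denom > 0, denom, np.inf)
    return int(np.argmax(r))


def binarize(position: np.ndarray) -> np.ndarray:
    """Sigmoid transfer s(x)=1/(1+e^-x) thresholded at 0.5, i.e. x > 0."""
    return np.asarray(position) > 0.0


def _knn_predict(Xtr, ytr, Xte, k=5):
    """Vectorized k-NN majority vote (ties break toward class 0)."""
    D = cdist(Xte, Xtr, "sqeuclidean")
    k = min(k, Xtr.shape[0])
    nn = np.argpartition(D, k - 1, axis=1)[:, :k]
    votes = ytr[nn].sum(axis=1)
    return (votes * 2 > k).astype(int)


class FitnessEvaluator:
    """Cached wrapper fitness over masks of a fixed training table.

    Inner folds are stratified and frozen at construction so every mask is
    scored on the identical splits; results are cached by mask bytes.
    """

    def __init__(self, X, y, inner_folds: int = 3, knn_k: int = 5, seed: int = 0):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.knn_k = knn_k
        skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        self.folds = [(tr, te) for tr, te in skf.split(self.X, self.y)]
        self.repair_index = repair_feature(self.X, self.y)
        self.cache: dict[bytes, float] = {}
        self.n_evals = 0
        self.n_repairs = 0

    def repair(self, mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            self.n_repairs += 1
            mask = mask.copy()
            mask[self.repair_index] = True
        return mask

    def __call__(self, mask: np.ndarray) -> float:
        mask = self.repair(np.asarray(mask, dtype=bool))
        key = mask.tobytes()
        if key in self.cache:
            return self.cache[key]
        Xm = self.X[:, mask]
        accs = []
        for tr, te in self.folds:
            pred = _knn_predict(Xm[tr], self.y[tr], Xm[te], self.knn_k)
            accs.append(np.mean(pred == self.y[te]) * 100.0)
        value = float(np.mean(accs))
        self.cache[key] = value
        self.n_evals += 1
        return value

    def position_fitness(self, position: np.ndarray) -> float:
        return self(binarize(position))


def fitness(mask, dataset: LabeledDataset, inner_folds: int = 3,
            knn_k: int = 5, seed: int = 0) -> float:
    """One-shot wrapper fitness of a mask on a dataset (percentage)."""
    ev = FitnessEvaluator(dataset.features, dataset.labels,
                          inner_folds=inner_folds, knn_k=knn_k, seed=seed)
    return ev(np.asarray(mask, dtype=bool))


# ---------------------------------------------------------------------------
# Levy flights
# ---------------------------------------------------------------------------

def levy_step(rng: np.random.Generator, lam: float = 1.5, alpha: float = 0.5,
              dim: int = 1) -> np.ndarray:
    """Mantegna-generated heavy-tailed step, scaled by alpha.

    The step s = u / |v|^(1/lam) with u ~ N(0, sigma_u^2), v ~ N(0, 1) has a
    power-law tail P(|s| > t) ~ t^-lam.
    """
    if not 1.0 < lam <= 3.0:
        raise ValidationError("Levy exponent must lie in (1, 3]")
    if alpha < 0:
        raise ValidationError("step scale must be >= 0")
    sigma_u = (math.gamma(1 + lam) * math.sin(math.pi * lam / 2)
               / (math.gamma((1 + lam) / 2) * lam * 2 ** ((lam - 1) / 2))) ** (1 / lam)
    u = rng.normal(0.0, sigma_u, size=dim)
    v = rng.standard_normal(dim)
    return alpha * u / np.abs(v) ** (1.0 / lam)


# ---------------------------------------------------------------------------
# optimizer core
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    mask: np.ndarray
    indices: np.ndarray
    fitness: float
    trace: list[float]
    n_evals: int
    n_repairs: int = 0


@dataclass
class OptimizerState:
    """Population positions/velocities, fitnesses, elitist best, iteration."""

    positions: np.ndarray
    fitnesses: np.ndarray
    velocities: np.ndarray | None = None
    best_position: np.ndarray | None = None
    best_fitness: float = -np.inf
    iteration: int = 0
    extras: dict = field(default_factory=dict)

    def update_best(self):
        i = int(np.argmax(self.fitnesses))
        if self.fitnesses[i] > self.best_fitness:
            self.best_fitness = float(self.fitnesses[i])
            self.best_position = self.positions[i].copy()


def _clamp(P: np.ndarray) -> np.ndarray:
    return np.clip(P, BOUNDS[0], BOUNDS[1])


class BaseSelector:
    """Shared init/evaluate/loop machinery; subclasses implement one iteration.

    Subclasses operate on a generic continuous objective (maximized), so the
    same dynamics drive both feature-subset search (via the sigmoid transfer)
    and the continuous benchmark functions used to validate the optimizers.
    """

    name = "base"
    pop_size = 100
    max_iter = 200

    def __init__(self, pop_size: int | None = None, max_iter: int | None = None,
                 **params):
        if pop_size is not None:
            self.pop_size = pop_size
        if max_iter is not None:
            self.max_iter = max_iter
        self.params = params
        self.uses_velocity = False

    # -- continuous optimization ------------------------------------------
    def init_state(self, objective, dim: int, rng) -> OptimizerState:
        P = rng.uniform(BOUNDS[0], BOUNDS[1], size=(self.pop_size, dim))
        F = np.array([objective(p) for p in P])
        # velocity-based selectors start with small random velocities, the
        # usual swarm convention; pure zero-velocity starts converge
        # prematurely on high-dimensional mask problems
        V = rng.uniform(-1.0, 1.0, size=P.shape) if self.uses_velocity else None
        st = OptimizerState(positions=P, fitnesses=F, velocities=V)
        st.update_best()
        return st

    def iterate(self, state: OptimizerState, objective, rng) -> OptimizerState:
        raise NotImplementedError

    def optimize(self, objective, dim: int, rng) -> tuple[OptimizerState, list[float]]:
        state = self.init_state(objective, dim, rng)
        self.setup(state, rng)
        trace = [state.best_fitness]
        for _ in range(self.max_iter):
            state = self.iterate(state, objective, rng)
            state.iteration += 1
            state.update_best()
            trace.append(state.best_fitness)
        return state, trace

    def setup(self, state: OptimizerState, rng) -> None:
        """Per-run constants drawn once (overridden where needed)."""

    # -- feature selection -------------------------------------------------
    def select(self, X, y, rng, inner_folds: int = 3, knn_k: int = 5,
               fitness_seed: int = 0) -> SelectionResult:
        X = np.asarray(X, dtype=float)
        ev = FitnessEvaluator(X, y, inner_folds=inner_folds, knn_k=knn_k,
                              seed=fitness_seed)
        state, trace = self.optimize(ev.position_fitness, X.shape[1], rng)
        mask = ev.repair(binarize(state.best_position))
        return SelectionResult(mask=mask, indices=np.flatnonzero(mask),
                               fitness=state.best_fitness, trace=trace,
                               n_evals=ev.n_evals, n_repairs=ev.n_repairs)


# ---------------------------------------------------------------------------
# cuckoo search
# ---------------------------------------------------------------------------

class CsoSelector(BaseSelector):
    """Cuckoo search: Levy-flight proposals + abandonment difference walk."""

    name = "cso"

    def __init__(self, pop_size=100, max_iter=200, alpha: float = 0.5,
                 lam: float = 1.5, p_a: float = 0.25, **params):
        super().__init__(pop_size, max_iter, **params)
        self.alpha = alpha
        self.lam = lam
        self.p_a = p_a

    def _levy_phase(self, state, objective, rng):
        N, dim = state.positions.shape
        for i in range(N):
            step = levy_step(rng, self.lam, self.alpha, dim)
            cand = _clamp(state.positions[i] + step)
            if np.array_equal(cand, state.positions[i]):
                continue        # no movement proposed, nothing to accept
            f = objective(cand)
            j = int(rng.integers(N))           # greedy vs a random nest
            if f > state.fitnesses[j]:
                state.positions[j] = cand
                state.fitnesses[j] = f

    def _abandon_phase(self, state, objective, rng):
        N, dim = state.positions.shape
        n_drop = int(round(self.p_a * N))
        if n_drop == 0:
            return
        worst = np.argsort(state.fitnesses)[:n_drop]
        for i in worst:
            gamma = rng.uniform()
            eps = rng.uniform()
            gate = 1.0 if self.p_a - eps > 0 else 0.0     # Heaviside gate
            a, b = rng.integers(N, size=2)
            cand = _clamp(state.positions[i]
                          + gamma * gate * (state.positions[a] - state.positions[b]))
            state.positions[i] = cand
            state.fitnesses[i] = objective(cand)

    def iterate(self, state, objective, rng):
        self._levy_phase(state, objective, rng)
        self._abandon_phase(state, objective, rng)
        return state


# ---------------------------------------------------------------------------
# rat swarm
# ---------------------------------------------------------------------------

class RsoSelector(BaseSelector):
    """Rat swarm: best-guided update with linearly decaying control scalar.

    R = Q * R_k + W * (R_best - R_k) with Q = A - z*A/T (A drawn once per run
    in [0, 1]) and W = 2*rand; proposal R_best - R, greedy-accepted.
    """

    name = "rso"

    def __init__(self, pop_size=100, max_iter=200, **params):
        super().__init__(pop_size, max_iter, **params)

    def setup(self, state, rng):
        state.extras["A"] = float(rng.uniform(0.0, 1.0))

    def iterate(self, state, objective, rng):
        N, dim = state.positions.shape
        A = state.extras["A"]
        Q = A - state.iteration * A / self.max_iter
        best = state.best_position
        for i in range(N):
            W = 2.0 * rng.uniform(size=dim)
            R = Q * state.positions[i] + W * (best - state.positions[i])
            cand = _clamp(best - R)
            f = objective(cand)
            if f > state.fitnesses[i]:          # greedy acceptance
                state.positions[i] = cand
                state.fitnesses[i] = f
        return state


class CsoRsoSelector(CsoSelector):
    """Hybrid cuckoo/rat-swarm: one shared population, both proposals per
    agent each iteration, keeping the better of the two (greedy), followed
    by the cuckoo abandonment walk (the hybrid keeps the discovery
    probability in its stated parameter set)."""

    name = "cso_rso"

    def setup(self, state, rng):
        state.extras["A"] = float(rng.uniform(0.0, 1.0))

    def iterate(self, state, objective, rng):
        N, dim = state.positions.shape
        A = state.extras["A"]
        Q = A - state.iteration * A / self.max_iter
        best = state.best_position
        for i in range(N):
            levy_cand = _clamp(state.positions[i]
                               + levy_step(rng, self.lam, self.alpha, dim))
            W = 2.0 * rng.uniform(size=dim)
            R = Q * state.positions[i] + W * (best - state.positions[i])
            rso_cand = _clamp(best - R)
            f1, f2 = objective(levy_cand), objective(rso_cand)
            cand, f = (levy_cand, f1) if f1 >= f2 else (rso_cand, f2)
            if f > state.fitnesses[i]:
                state.positions[i] = cand
                state.fitnesses[i] = f
        self._abandon_phase(state, objective, rng)
        return state


# ---------------------------------------------------------------------------
# zebra optimization
# ---------------------------------------------------------------------------

class ZoaSelector(BaseSelector):
    """Zebra optimization: foraging toward the pioneer, then defense.

    Phase 1 moves each zebra toward the pioneer (population best) with
    per-dimension random scale r and J in {1, 2}; phase 2 applies either a
    time-shrinking self-perturbation (S1) or a random-zebra-guided move (S2)
    depending on a per-agent draw Ps; both phases are greedy-accepted.
    """

    name = "zoa"
    pop_size = 50
    max_iter = 100

    def __init__(self, pop_size=50, max_iter=100, C: float = 0.01, **params):
        super().__init__(pop_size, max_iter, **params)
        self.C = C

    def _greedy(self, state, i, cand, objective):
        f = objective(cand)
        if f > state.fitnesses[i]:
            state.positions[i] = cand
            state.fitnesses[i] = f

    def iterate(self, state, objective, rng):
        N, dim = state.positions.shape
        t, T = state.iteration + 1, self.max_iter
        pioneer = state.positions[int(np.argmax(state.fitnesses))].copy()
        for i in range(N):                      # phase 1: foraging
            r = rng.uniform(size=dim)
            J = int(round(1 + rng.uniform()))
            cand = _clamp(state.positions[i]
                          + r * (pioneer - J * state.positions[i]))
            self._greedy(state, i, cand, objective)
        for i in range(N):                      # phase 2: defense
            Ps = rng.uniform()
            if Ps <= 0.5:                       # S1: escape (shrinking)
                r = rng.uniform(size=dim)
                cand = state.positions[i] + self.C * (2 * r - 1) \
                    * (1 - t / T) * state.positions[i]
            else:                               # S2: scare (random-guided)
                r = rng.uniform(size=dim)
                J = int(round(1 + rng.uniform()))
                other = state.positions[int(rng.integers(N))]
                cand = state.positions[i] + r * (other - J * state.positions[i])
            self._greedy(state, i, _clamp(cand), objective)
        return state


# ---------------------------------------------------------------------------
# gravitational search
# ---------------------------------------------------------------------------

def gravitational_constant(iteration: int, max_iter: int, H0: float = 100.0,
                           beta: float = 20.0) -> float:
    """Attractional constant H(n) = H0 * exp(-beta * n / T)."""
    return H0 * math.exp(-beta * iteration / max_iter)


def gsa_masses(fitnesses: np.ndarray) -> np.ndarray:
    """Normalized gravitational masses from fitness (flat population: 1/N)."""
    f = np.asarray(fitnesses, dtype=float)
    best, worst = f.max(), f.min()
    if best == worst:
        return np.full(f.shape, 1.0 / f.size)
    m = (f - worst) / (best - worst)
    return m / m.sum()


class GsaSelector(BaseSelector):
    """Gravitational search: mass-weighted attraction with decaying constant."""

    name = "gsa"

    def __init__(self, pop_size=100, max_iter=200, H0: float = 100.0,
                 beta: float = 20.0, eps: float = 1e-9, **params):
        super().__init__(pop_size, max_iter, **params)
        self.H0 = H0
        self.beta = beta
        self.eps = eps
        self.uses_velocity = True

    def accelerations(self, state, rng):
        """a_i = sum_j rand_j * H * M_j * (x_j - x_i) / (E_ij + eps).

        The passive mass cancels against the division by the agent's own
        inertial mass (they are the same normalized mass), so the worst
        agent's zero mass causes no 0/0.
        """
        P = state.positions
        N = P.shape[0]
        M = gsa_masses(state.fitnesses)
        H = gravitational_constant(state.iteration, self.max_iter,
                                   self.H0, self.beta)
        E = cdist(P, P)
        acc = np.zeros_like(P)
        for i in range(N):
            randj = rng.uniform(size=N)
            coeff = randj * H * M / (E[i] + self.eps)
            coeff[i] = 0.0
            acc[i] = coeff @ (P - P[i])
        return acc

    def iterate(self, state, objective, rng):
        acc = self.accelerations(state, rng)
        randi = rng.uniform(size=(state.positions.shape[0], 1))
        state.velocities = randi * state.velocities + acc
        state.positions = _clamp(state.positions + state.velocities)
        state.fitnesses = np.array([objective(p) for p in state.positions])
        return state


# ---------------------------------------------------------------------------
# particle swarm
# ---------------------------------------------------------------------------

class PsoSelector(BaseSelector):
    """Particle swarm: inertia + cognitive (pbest) + social (gbest) velocity."""

    name = "pso"

    def __init__(self, pop_size=100, max_iter=200, theta: float = 0.5,
                 b1: float = 0.2, b2: float = 0.4, **params):
        super().__init__(pop_size, max_iter, **params)
        self.theta = theta
        self.b1 = b1
        self.b2 = b2
        self.uses_velocity = True

    def setup(self, state, rng):
        state.extras["pbest"] = state.positions.copy()
        state.extras["pbest_f"] = state.fitnesses.copy()

    def iterate(self, state, objective, rng):
        N, dim = state.positions.shape
        pbest, pbest_f = state.extras["pbest"], state.extras["pbest_f"]
        c1 = rng.uniform(size=(N, dim))
        c2 = rng.uniform(size=(N, dim))
        state.velocities = (self.theta * state.velocities
                            + self.b1 * c1 * (pbest - state.positions)
                            + self.b2 * c2 * (state.best_position - state.positions))
        state.positions = _clamp(state.positions + state.velocities)
        state.fitnesses = np.array([objective(p) for p in state.positions])
        improved = state.fitnesses > pbest_f
        pbest[improved] = state.positions[improved]
        pbest_f[improved] = state.fitnesses[improved]
        return state


class GsaPsoSelector(GsaSelector):
    """Hybrid: GSA acceleration in the cognitive slot, gbest in the social.

    v(n+1) = theta*v(n) + b1*c1*a_i(n) + b2*c2*(gbest - x_i(n)); the
    accelerations a_i are the gravitational ones of the parent GSA.
    """

    name = "gsa_pso"

    def __init__(self, pop_size=100, max_iter=200, theta: float = 0.5,
                 b1: float = 0.2, b2: float = 0.4, H0: float = 100.0,
                 beta: float = 20.0, eps: float = 1e-9, **params):
        super().__init__(pop_size, max_iter, H0=H0, beta=beta, eps=eps, **params)
        self.theta = theta
        self.b1 = b1
        self.b2 = b2

    def iterate(self, state, objective, rng):
        N, dim = state.positions.shape
        acc = self.accelerations(state, rng)
        c1 = rng.uniform(size=(N, dim))
        c2 = rng.uniform(size=(N, dim))
        state.velocities = (self.theta * state.velocities
                            + self.b1 * c1 * acc
                            + self.b2 * c2 * (state.best_position - state.positions))
        state.positions = _clamp(state.positions + state.velocities)
        state.fitnesses = np.array([objective(p) for p in state.positions])
        return state


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

class PassThroughSelector(BaseSelector):
    """Selects every feature; baseline / harness selector."""

    name = "none"

    def __init__(self, **params):
        super().__init__(pop_size=1, max_iter=0, **params)

    def select(self, X, y, rng, **kwargs):
        dim = np.asarray(X).shape[1]
        mask = np.ones(dim, dtype=bool)
        return SelectionResult(mask=mask, indices=np.arange(dim),
                               fitness=np.nan, trace=[], n_evals=0)


SELECTORS = {
    "cso": CsoSelector,
    "rso": RsoSelector,
    "cso_rso": CsoRsoSelector,
    "zoa": ZoaSelector,
    "gsa": GsaSelector,
    "pso": PsoSelector,
    "gsa_pso": GsaPsoSelector,
    "none": PassThroughSelector,
}


def make_selector(name: str, **params) -> BaseSelector:
    if name not in SELECTORS:
        raise ValidationError(f"unknown selector '{name}'")
    return SELECTORS[name](**params)
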