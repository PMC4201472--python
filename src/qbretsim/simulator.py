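"""Monte Carlo dynamics of donor/acceptor molecules on a hexagonal membrane.

Donor (luciferase-labeled) and acceptor (fluorophore-labeled) molecules
occupy cells of a periodic hexagonal lattice, one molecule per cell. Each
synchronous time step is the composition of three phases:

1. **move** — every monomer attempts one step to a uniformly random neighbor
   cell (rejected, not retried, if occupied); every dimer attempts one unit
   move, either a translation of both protomers in one random direction or a
   rotation of one protomer around its partner.
2. **association** — monomers, visited in a fresh random order, probe one
   random occupied neighbor; if that neighbor is also still a monomer the
   pair bonds with probability ``p_association`` of the pair type.
3. **dissociation** — each dimer independently breaks with probability
   ``p_dissociation`` of its type; the protomers stay in place as monomers.

The simulated BRET ratio is a pure adjacency count: the number of unordered
adjacent donor–acceptor cell pairs (bonded or incidental) divided by the
number of donors. Incidental adjacency must count — with all probabilities
zero the model still produces nonzero BRET from random collisions, which is
exactly the non-specific signal the analysis side has to recognize.

The inner loops are compiled with numba; molecule state lives in flat int32
arrays (occupancy grid, positions, species, partner index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .hexlattice import LatticeConfig

__all__ = [
    "InteractionParams",
    "NON_SPECIFIC",
    "SPECIFIC",
    "SimConfig",
    "SimState",
    "SimResult",
    "place_molecules",
    "move_phase",
    "association_phase",
    "dissociation_phase",
    "step",
    "compute_bret",
    "run",
    "run_replicates",
    "run_grid",
    "run_anticorrelated",
]

DONOR = 0
ACCEPTOR = 1

# Axial neighbor offsets, duplicated here as a module constant for numba.
_DQ = np.array([1, -1, 0, 0, 1, -1], dtype=np.int32)
_DR = np.array([0, 0, 1, -1, -1, 1], dtype=np.int32)

_SEED_MOD = 2**31  # numba's np.random.seed takes a 32-bit value


@dataclass(frozen=True)
class InteractionParams:
    """Per-step association/dissociation probabilities by species pair.

    Attributes are indexed by the unordered pair of species: donor–donor
    (``dd``), donor–acceptor (``da``), acceptor–acceptor (``aa``).
    """

    p_assoc_dd: float = 0.0
    p_assoc_da: float = 0.0
    p_assoc_aa: float = 0.0
    p_diss_dd: float = 0.0
    p_diss_da: float = 0.0
    p_diss_aa: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "p_assoc_dd",
            "p_assoc_da",
            "p_assoc_aa",
            "p_diss_dd",
            "p_diss_da",
            "p_diss_aa",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1], got {v}")

    def _assoc_matrix(self) -> np.ndarray:
        # symmetric 2x2: [species_a, species_b] -> p_association
        return np.array(
            [
                [self.p_assoc_dd, self.p_assoc_da],
                [self.p_assoc_da, self.p_assoc_aa],
            ],
            dtype=np.float64,
        )

    def _diss_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.p_diss_dd, self.p_diss_da],
                [self.p_diss_da, self.p_diss_aa],
            ],
            dtype=np.float64,
        )


#: Non-specific interaction: no bonds ever form; BRET is random adjacency only.
NON_SPECIFIC = InteractionParams()

#: Specific interaction: adjacent donor–acceptor monomers always bond and
#: never dissociate; like-species pairs never bond.
SPECIFIC = InteractionParams(p_assoc_da=1.0, p_diss_da=0.0)

PRESETS = {"non_specific": NON_SPECIFIC, "specific": SPECIFIC}


@dataclass(frozen=True)
class SimConfig:
    """Complete description of one simulation run."""

    n_donor: int
    n_acceptor: int
    params: InteractionParams = NON_SPECIFIC
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    n_steps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donor < 0 or self.n_acceptor < 0:
            raise ValueError("molecule counts must be nonnegative")
        if self.n_donor + self.n_acceptor > self.lattice.capacity:
            raise ValueError(
                f"{self.n_donor}+{self.n_acceptor} molecules exceed lattice "
                f"capacity {self.lattice.capacity}"
            )
        if self.n_steps < 0:
            raise ValueError("n_steps must be nonnegative")


@dataclass
class SimState:
    """Occupancy and molecule registry for one lattice.

    ``grid`` maps flattened cell index ``q * height + r`` to molecule id or
    -1; ``q``/``r`` hold each molecule's axial coordinates; ``species`` is 0
    for donor, 1 for acceptor; ``partner`` is the bonded molecule id or -1.
    """

    lattice: LatticeConfig
    grid: np.ndarray
    q: np.ndarray
    r: np.ndarray
    species: np.ndarray
    partner: np.ndarray

    @property
    def n_molecules(self) -> int:
        return len(self.species)

    @property
    def n_donor(self) -> int:
        return int(np.sum(self.species == DONOR))

    @property
    def n_acceptor(self) -> int:
        return int(np.sum(self.species == ACCEPTOR))

    @property
    def n_dimers(self) -> int:
        return int(np.sum(self.partner >= 0)) // 2

    def validate(self) -> None:
        """Assert the occupancy/partnership invariants; raise on violation."""
        W, H = self.lattice.width, self.lattice.height
        occupied = np.flatnonzero(self.grid >= 0)
        if len(occupied) != self.n_molecules:
            raise AssertionError("occupancy map does not match molecule count")
        for i in range(self.n_molecules):
            idx = self.q[i] * H + self.r[i]
            if self.grid[idx] != i:
                raise AssertionError(f"molecule {i} position inconsistent with grid")
            p = self.partner[i]
            if p >= 0:
                if self.partner[p] != i:
                    raise AssertionError(f"partnership of {i} not symmetric")
                from .hexlattice import hex_distance

                d = hex_distance(
                    self.lattice,
                    (int(self.q[i]), int(self.r[i])),
                    (int(self.q[p]), int(self.r[p])),
                )
                if d != 1:
                    raise AssertionError(f"dimer {i}-{p} not adjacent (distance {d})")


@dataclass(frozen=True)
class SimResult:
    """Outcome of one run: final BRET ratio plus bookkeeping."""

    bret: float
    n_donor: int
    n_acceptor: int
    n_dimers_final: int
    seed: int


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _nb_seed(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _nb_place(grid, q, r, species, n_donor, n_acceptor, W, H):
    """Uniform placement without replacement via partial Fisher-Yates."""
    n = n_donor + n_acceptor
    cells = np.arange(W * H, dtype=np.int32)
    for i in range(n):
        j = i + np.random.randint(0, W * H - i)
        cells[i], cells[j] = cells[j], cells[i]
        idx = cells[i]
        grid[idx] = i
        q[i] = idx // H
        r[i] = idx % H
        species[i] = DONOR if i < n_donor else ACCEPTOR


@njit(cache=True)
def _nb_move_phase(grid, q, r, partner, W, H):
    n = len(q)
    # movers: every monomer, plus one representative per dimer (lower id)
    movers = np.empty(n, dtype=np.int32)
    m = 0
    for i in range(n):
        if partner[i] < 0 or partner[i] > i:
            movers[m] = i
            m += 1
    perm = np.random.permutation(m)
    for k in range(m):
        i = movers[perm[k]]
        p = partner[i]
        if p < 0:
            # monomer: one attempt at a random neighbor
            d = np.random.randint(0, 6)
            nq = (q[i] + _DQ[d]) % W
            nr = (r[i] + _DR[d]) % H
            nidx = nq * H + nr
            if grid[nidx] < 0:
                grid[q[i] * H + r[i]] = -1
                grid[nidx] = i
                q[i] = nq
                r[i] = nr
        else:
            if np.random.randint(0, 2) == 0:
                # translation: both protomers shift by one random direction;
                # destinations must be free or vacated by the dimer itself
                d = np.random.randint(0, 6)
                aq = (q[i] + _DQ[d]) % W
                ar = (r[i] + _DR[d]) % H
                bq = (q[p] + _DQ[d]) % W
                br = (r[p] + _DR[d]) % H
                aidx = aq * H + ar
                bidx = bq * H + br
                iidx = q[i] * H + r[i]
                pidx = q[p] * H + r[p]
                ok_a = grid[aidx] < 0 or aidx == pidx
                ok_b = grid[bidx] < 0 or bidx == iidx
                if ok_a and ok_b:
                    grid[iidx] = -1
                    grid[pidx] = -1
                    grid[aidx] = i
                    grid[bidx] = p
                    q[i], r[i] = aq, ar
                    q[p], r[p] = bq, br
            else:
                # rotation: a random protomer steps to a random free cell
                # adjacent to its partner (stays bonded, stays adjacent)
                if np.random.randint(0, 2) == 0:
                    mv, anchor = i, p
                else:
                    mv, anchor = p, i
                free = np.empty(6, dtype=np.int32)
                nf = 0
                for d in range(6):
                    nq = (q[anchor] + _DQ[d]) % W
                    nr = (r[anchor] + _DR[d]) % H
                    nidx = nq * H + nr
                    if grid[nidx] < 0:
                        free[nf] = nidx
                        nf += 1
                if nf > 0:
                    dest = free[np.random.randint(0, nf)]
                    grid[q[mv] * H + r[mv]] = -1
                    grid[dest] = mv
                    q[mv] = dest // H
                    r[mv] = dest % H


@njit(cache=True)
def _nb_assoc_phase(grid, q, r, species, partner, p_assoc, W, H):
    n = len(q)
    monomers = np.empty(n, dtype=np.int32)
    m = 0
    for i in range(n):
        if partner[i] < 0:
            monomers[m] = i
            m += 1
    perm = np.random.permutation(m)
    for k in range(m):
        i = monomers[perm[k]]
        if partner[i] >= 0:  # dimerized earlier this phase
            continue
        occ = np.empty(6, dtype=np.int32)
        no = 0
        for d in range(6):
            nq = (q[i] + _DQ[d]) % W
            nr = (r[i] + _DR[d]) % H
            j = grid[nq * H + nr]
            if j >= 0:
                occ[no] = j
                no += 1
        if no == 0:
            continue
        j = occ[np.random.randint(0, no)]
        if partner[j] >= 0:  # only monomers can pair
            continue
        p = p_assoc[species[i], species[j]]
        if p > 0.0 and np.random.random() < p:
            partner[i] = j
            partner[j] = i


@njit(cache=True)
def _nb_diss_phase(partner, species, p_diss):
    n = len(partner)
    for i in range(n):
        p = partner[i]
        if p > i:  # one visit per dimer
            pd = p_diss[species[i], species[p]]
            if pd > 0.0 and np.random.random() < pd:
                partner[i] = -1
                partner[p] = -1


@njit(cache=True)
def _nb_bret_pairs(grid, q, r, species, W, H):
    """Count unordered adjacent donor-acceptor cell pairs (donor side)."""
    n = len(q)
    pairs = 0
    for i in range(n):
        if species[i] != DONOR:
            continue
        for d in range(6):
            nq = (q[i] + _DQ[d]) % W
            nr = (r[i] + _DR[d]) % H
            j = grid[nq * H + nr]
            if j >= 0 and species[j] == ACCEPTOR:
                pairs += 1
    return pairs


@njit(cache=True)
def _nb_run(n_donor, n_acceptor, p_assoc, p_diss, W, H, n_steps, seed):
    np.random.seed(seed)
    n = n_donor + n_acceptor
    grid = np.full(W * H, -1, dtype=np.int32)
    q = np.empty(n, dtype=np.int32)
    r = np.empty(n, dtype=np.int32)
    species = np.empty(n, dtype=np.int32)
    partner = np.full(n, -1, dtype=np.int32)
    _nb_place(grid, q, r, species, n_donor, n_acceptor, W, H)
    for _ in range(n_steps):
        _nb_move_phase(grid, q, r, partner, W, H)
        _nb_assoc_phase(grid, q, r, species, partner, p_assoc, W, H)
        _nb_diss_phase(partner, species, p_diss)
    pairs = _nb_bret_pairs(grid, q, r, species, W, H)
    n_dimers = 0
    for i in range(n):
        if partner[i] >= 0:
            n_dimers += 1
    return pairs, n_dimers // 2


# ---------------------------------------------------------------------------
# Python API
# ---------------------------------------------------------------------------


def _seed_from_rng(rng: np.random.Generator) -> int:
    return int(rng.integers(0, _SEED_MOD))


def _empty_state(config: SimConfig) -> SimState:
    W, H = config.lattice.width, config.lattice.height
    n = config.n_donor + config.n_acceptor
    return SimState(
        lattice=config.lattice,
        grid=np.full(W * H, -1, dtype=np.int32),
        q=np.empty(n, dtype=np.int32),
        r=np.empty(n, dtype=np.int32),
        species=np.empty(n, dtype=np.int32),
        partner=np.full(n, -1, dtype=np.int32),
    )


def place_molecules(config: SimConfig, rng: np.random.Generator) -> SimState:
    """Place ``n_donor`` donors and ``n_acceptor`` acceptors uniformly at
    random on distinct cells; all molecules start as monomers."""
    state = _empty_state(config)
    W, H = config.lattice.width, config.lattice.height
    _nb_seed(_seed_from_rng(rng))
    _nb_place(
        state.grid, state.q, state.r, state.species,
        config.n_donor, config.n_acceptor, W, H,
    )
    return state


def move_phase(state: SimState, rng: np.random.Generator) -> SimState:
    """One movement phase, in place: monomer steps and dimer translations or
    rotations, each attempted once and rejected (not retried) on collision."""
    _nb_seed(_seed_from_rng(rng))
    _nb_move_phase(
        state.grid, state.q, state.r, state.partner,
        state.lattice.width, state.lattice.height,
    )
    return state


def association_phase(
    state: SimState, params: InteractionParams, rng: np.random.Generator
) -> SimState:
    """One association phase, in place: monomers in random order each probe
    one random occupied neighbor and bond with the pair-type probability."""
    _nb_seed(_seed_from_rng(rng))
    _nb_assoc_phase(
        state.grid, state.q, state.r, state.species, state.partner,
        params._assoc_matrix(), state.lattice.width, state.lattice.height,
    )
    return state


def dissociation_phase(
    state: SimState, params: InteractionParams, rng: np.random.Generator
) -> SimState:
    """One dissociation phase, in place: each dimer independently breaks
    with the pair-type probability; protomers stay on their cells."""
    _nb_seed(_seed_from_rng(rng))
    _nb_diss_phase(state.partner, state.species, params._diss_matrix())
    return state


def step(
    state: SimState, params: InteractionParams, rng: np.random.Generator
) -> SimState:
    """One synchronous time step: move, then associate, then dissociate."""
    move_phase(state, rng)
    association_phase(state, params, rng)
    dissociation_phase(state, params, rng)
    return state


def compute_bret(state: SimState) -> float:
    """Simulated BRET ratio: adjacent donor–acceptor cell pairs / donors.

    Counts every unordered pair of adjacent cells holding one donor and one
    acceptor, bonded or merely adjacent; a donor with k adjacent acceptors
    contributes k pairs.
    """
    n_donor = state.n_donor
    if n_donor == 0:
        raise ValueError("BRET ratio undefined without donor molecules")
    pairs = _nb_bret_pairs(
        state.grid, state.q, state.r, state.species,
        state.lattice.width, state.lattice.height,
    )
    return pairs / n_donor


def run(config: SimConfig) -> SimResult:
    """Run one full simulation and return the final-snapshot BRET ratio.

    Identical ``config`` (including seed) gives a bit-identical result.
    """
    if config.n_donor == 0:
        raise ValueError("BRET ratio undefined without donor molecules")
    pairs, n_dimers = _nb_run(
        config.n_donor,
        config.n_acceptor,
        config.params._assoc_matrix(),
        config.params._diss_matrix(),
        config.lattice.width,
        config.lattice.height,
        config.n_steps,
        config.seed % _SEED_MOD,
    )
    return SimResult(
        bret=pairs / config.n_donor,
        n_donor=config.n_donor,
        n_acceptor=config.n_acceptor,
        n_dimers_final=n_dimers,
        seed=config.seed,
    )


def _derive_seed(master_seed: int, counter: int) -> int:
    """Stable per-run seed: SeedSequence(master, counter) -> 31-bit int."""
    ss = np.random.SeedSequence([master_seed, counter])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % _SEED_MOD)


def run_replicates(
    config: SimConfig, n_rep: int = 5
) -> tuple[float, float, list[SimResult]]:
    """Run ``n_rep`` independent replicates with seeds derived from
    ``config.seed``; return (mean BRET, SEM, individual results).

    SEM is 0.0 by convention for a single replicate.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    results = []
    for k in range(n_rep):
        cfg = SimConfig(
            n_donor=config.n_donor,
            n_acceptor=config.n_acceptor,
            params=config.params,
            lattice=config.lattice,
            n_steps=config.n_steps,
            seed=_derive_seed(config.seed, k),
        )
        results.append(run(cfg))
    brets = np.array([res.bret for res in results])
    mean = float(brets.mean())
    sem = float(brets.std(ddof=1) / np.sqrt(n_rep)) if n_rep > 1 else 0.0
    return mean, sem, results


def run_grid(
    donor_levels,
    acceptor_levels,
    params: InteractionParams,
    n_rep: int = 5,
    lattice: LatticeConfig | None = None,
    n_steps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full factorial sweep over donor and acceptor counts.

    Returns a tidy table with one row per (n_donor, n_acceptor, replicate);
    aggregate with groupby for mean +/- SEM. Per-run seeds are derived from
    ``seed`` by a deterministic counter so sweeps are reproducible.
    """
    donor_levels = list(donor_levels)
    acceptor_levels = list(acceptor_levels)
    if not donor_levels or not acceptor_levels:
        raise ValueError("level lists must be nonempty")
    lattice = lattice or LatticeConfig()
    rows = []
    counter = 0
    for nd in donor_levels:
        for na in acceptor_levels:
            for rep in range(n_rep):
                s = _derive_seed(seed, counter)
                counter += 1
                res = run(
                    SimConfig(
                        n_donor=int(nd), n_acceptor=int(na), params=params,
                        lattice=lattice, n_steps=n_steps, seed=s,
                    )
                )
                rows.append(
                    {
                        "n_donor": int(nd),
                        "n_acceptor": int(na),
                        "replicate": rep,
                        "seed": s,
                        "bret": res.bret,
                        "n_dimers_final": res.n_dimers_final,
                    }
                )
    return pd.DataFrame(rows)


def run_anticorrelated(
    total: int,
    donor_levels,
    params: InteractionParams,
    n_rep: int = 5,
    lattice: LatticeConfig | None = None,
    n_steps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sweep with the total donor+acceptor amount fixed: for each donor level
    the acceptor count is ``total - n_donor`` (the anticorrelated-expression
    scenario in which donor expression falls as acceptor expression rises)."""
    donor_levels = list(donor_levels)
    if not donor_levels:
        raise ValueError("donor_levels must be nonempty")
    for nd in donor_levels:
        if nd >= total:
            raise ValueError(f"donor level {nd} must be < total {total}")
    lattice = lattice or LatticeConfig()
    rows = []
    counter = 0
    for nd in donor_levels:
        na = total - int(nd)
        for rep in range(n_rep):
            s = _derive_seed(seed, counter)
            counter += 1
            res = run(
                SimConfig(
                    n_donor=int(nd), n_acceptor=na, params=params,
                    lattice=lattice, n_steps=n_steps, seed=s,
                )
            )
            rows.append(
                {
                    "n_donor": int(nd),
                    "n_acceptor": na,
                    "replicate": rep,
                    "seed": s,
                    "bret": res.bret,
                    "n_dimers_final": res.n_dimers_final,
                }
            )
    return pd.DataFrame(rows)
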