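"""Superpixel clustering with a GA-seeded self-generating neural forest.

A self-generating neural tree (SGNT) is an incremental hierarchical
clustering structure: every sample becomes a leaf, every internal neuron's
weight is the mean of the leaves it covers, and each tree root defines one
cluster. A forest of K trees (SGNF) is grown by inserting samples one at a
time: the sample attaches next to the globally nearest neuron across all
trees, so cluster membership follows nearest-neighbour chaining.

The forest an insertion order produces depends on which K samples seed the
trees, so seed choice is posed as an optimisation problem and solved with
a genetic algorithm: chromosomes are K-subsets of sample indices, fitness
is φ(C) = 1 / (1 + δ²) with δ² the per-cluster-normalised within-cluster
scatter

    δ² = Σ_i Σ_j ‖x_ij, r_i‖² / n_i,

and evolution uses roulette-wheel selection, single-point crossover and
per-gene mutation. The sample distance is the dimension-normalised
Euclidean ‖Xi, Xj‖ = sqrt(Σ_k (w_jk − w_ik)² / p).

Feature columns are min–max scaled to [0, 1] before clustering so pixel
coordinates do not dominate intensity.

The forest build exists twice on purpose: a plain-Python
:class:`NeuralForest` that exposes the tree structure for inspection, and
a numba kernel (:func:`build_assignment`) used in the GA inner loop; the
tests assert the two agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from numba import njit

from .stackio import StackValidationError

__all__ = [
    "Neuron",
    "NeuralForest",
    "Chromosome",
    "sample_distance",
    "sgnt_insert",
    "cluster_assignment",
    "build_assignment",
    "scatter",
    "fitness",
    "ga_select_seeds",
    "refine_seeds",
    "exhaustive_best_seeds",
    "normalize_features",
    "make_model_consistency_objective",
    "cluster_superpixels",
]


def sample_distance(xi: np.ndarray, xj: np.ndarray, p: int | None = None) -> float:
    """Dimension-normalised Euclidean distance ‖Xi, Xj‖."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise StackValidationError(f"dimension mismatch: {xi.shape} vs {xj.shape}")
    if p is None:
        p = xi.size
    elif p != xi.size:
        raise StackValidationError(f"vectors have {xi.size} attributes, expected p={p}")
    return math.sqrt(float(np.sum((xj - xi) ** 2)) / p)


@dataclass
class Neuron:
    """One neuron: weight vector, children, and (for leaves) its sample."""

    w: np.ndarray
    children: list[int] = field(default_factory=list)
    parent: int = -1
    tree: int = 0
    sample_ref: int | None = None
    leaf_count: int = 1

    @property
    def is_leaf(self) -> bool:
        return not self.children


class NeuralForest:
    """K self-generating neural trees over p-dimensional samples.

    Roots are the first K neurons (node i is the root of tree i); node
    indices double as creation order, which is the tie-break for nearest
    neuron searches.
    """

    def __init__(self, samples: np.ndarray, seed_ids) -> None:
        samples = np.asarray(samples, dtype=float)
        seed_ids = list(seed_ids)
        if len(seed_ids) == 0:
            raise StackValidationError("forest needs at least one seed")
        if len(set(seed_ids)) != len(seed_ids):
            raise StackValidationError("seed ids must be distinct")
        self.p = samples.shape[1]
        self.n_trees = len(seed_ids)
        self.nodes: list[Neuron] = [
            Neuron(w=samples[sid].copy(), tree=i, sample_ref=int(sid))
            for i, sid in enumerate(seed_ids)
        ]
        self._sample_leaf: dict[int, int] = {int(s): i for i, s in enumerate(seed_ids)}

    @property
    def roots(self) -> list[int]:
        return list(range(self.n_trees))

    def nearest_neuron(self, x: np.ndarray) -> int:
        """Globally nearest neuron; ties broken by earliest creation."""
        best, best_d = 0, math.inf
        for i, node in enumerate(self.nodes):
            d = sample_distance(x, node.w, self.p)
            if d < best_d:
                best, best_d = i, d
        return best

    def insert(self, x: np.ndarray, sample_id: int) -> None:
        """Insert one sample as a new leaf next to its nearest neuron."""
        x = np.asarray(x, dtype=float)
        win = self.nearest_neuron(x)
        winner = self.nodes[win]
        if winner.is_leaf:
            # the winner becomes internal; a copy-neuron keeps its sample
            copy = Neuron(
                w=winner.w.copy(),
                parent=win,
                tree=winner.tree,
                sample_ref=winner.sample_ref,
            )
            ci = len(self.nodes)
            self.nodes.append(copy)
            winner.children.append(ci)
            if winner.sample_ref is not None:
                self._sample_leaf[winner.sample_ref] = ci
            winner.sample_ref = None
        leaf = Neuron(w=x.copy(), parent=win, tree=winner.tree, sample_ref=int(sample_id))
        li = len(self.nodes)
        self.nodes.append(leaf)
        winner.children.append(li)
        self._sample_leaf[int(sample_id)] = li
        # restore the leaf-average invariant on the path to the root
        node = win
        while node != -1:
            n = self.nodes[node]
            n.w = (n.w * n.leaf_count + x) / (n.leaf_count + 1)
            n.leaf_count += 1
            node = n.parent

    def assignment(self) -> dict[int, int]:
        """Map sample id → tree index (cluster)."""
        return {sid: self.nodes[leaf].tree for sid, leaf in self._sample_leaf.items()}

    def leaves_under(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            i = stack.pop()
            n = self.nodes[i]
            if n.is_leaf:
                out.append(i)
            else:
                stack.extend(n.children)
        return out


def sgnt_insert(forest: NeuralForest, sample: np.ndarray, sample_id: int) -> NeuralForest:
    """Functional wrapper over :meth:`NeuralForest.insert`."""
    if not isinstance(forest, NeuralForest) or not forest.nodes:
        raise StackValidationError("forest must be initialised with seed leaves")
    forest.insert(sample, sample_id)
    return forest


def cluster_assignment(forest: NeuralForest) -> dict[int, int]:
    """Partition of inserted sample ids by containing tree."""
    return forest.assignment()


@njit(cache=True)
def build_assignment(samples, seed_ids):  # pragma: no cover - exercised via tests
    """Numba kernel: grow the forest and return each sample's tree index.

    Remaining samples are inserted in ascending sample id (the canonical
    order), matching :class:`NeuralForest` insertion exactly.
    """
    L, p = samples.shape
    K = seed_ids.shape[0]
    max_nodes = K + 2 * (L - K) + 1
    W = np.empty((max_nodes, p))
    parent = np.full(max_nodes, -1, np.int64)
    tree = np.zeros(max_nodes, np.int64)
    is_leaf = np.zeros(max_nodes, np.bool_)
    leaf_cnt = np.zeros(max_nodes, np.int64)
    assign = np.full(L, -1, np.int64)
    is_seed = np.zeros(L, np.bool_)
    for i in range(K):
        sid = seed_ids[i]
        for a in range(p):
            W[i, a] = samples[sid, a]
        tree[i] = i
        is_leaf[i] = True
        leaf_cnt[i] = 1
        assign[sid] = i
        is_seed[sid] = True
    n_nodes = K
    for sid in range(L):
        if is_seed[sid]:
            continue
        x = samples[sid]
        best = 0
        best_d = 1e300
        for ni in range(n_nodes):
            d = 0.0
            for a in range(p):
                diff = x[a] - W[ni, a]
                d += diff * diff
            if d < best_d:
                best_d = d
                best = ni
        if is_leaf[best]:
            c = n_nodes
            n_nodes += 1
            for a in range(p):
                W[c, a] = W[best, a]
            parent[c] = best
            tree[c] = tree[best]
            is_leaf[c] = True
            leaf_cnt[c] = 1
            is_leaf[best] = False
        nl = n_nodes
        n_nodes += 1
        for a in range(p):
            W[nl, a] = x[a]
        parent[nl] = best
        tree[nl] = tree[best]
        is_leaf[nl] = True
        leaf_cnt[nl] = 1
        assign[sid] = tree[best]
        node = best
        while node != -1:
            cnt = leaf_cnt[node]
            for a in range(p):
                W[node, a] = (W[node, a] * cnt + x[a]) / (cnt + 1)
            leaf_cnt[node] = cnt + 1
            node = parent[node]
    return assign


def scatter(samples: np.ndarray, assignment: np.ndarray, centers: np.ndarray) -> float:
    """Within-cluster scatter δ² = Σ_i Σ_j ‖x_ij, r_i‖² / n_i.

    Empty clusters contribute 0.
    """
    samples = np.asarray(samples, dtype=float)
    assignment = np.asarray(assignment)
    centers = np.asarray(centers, dtype=float)
    p = samples.shape[1]
    total = 0.0
    for i in range(centers.shape[0]):
        members = samples[assignment == i]
        if members.shape[0] == 0:
            continue
        sq = np.sum((members - centers[i]) ** 2, axis=1) / p
        total += float(sq.mean())
    return total


@dataclass
class Chromosome:
    """An ordered selection of K distinct sample indices acting as seeds."""

    seed_ids: tuple
    fitness: float = math.nan
    best_per_generation: list = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.seed_ids = tuple(int(s) for s in self.seed_ids)
        if len(set(self.seed_ids)) != len(self.seed_ids):
            raise StackValidationError("chromosome seed ids must be distinct")


def _forest_scatter(samples: np.ndarray, seed_ids: np.ndarray) -> tuple[np.ndarray, float]:
    assign = build_assignment(samples, seed_ids)
    K = len(seed_ids)
    centers = np.empty((K, samples.shape[1]))
    for i in range(K):
        members = samples[assign == i]
        centers[i] = members.mean(axis=0) if members.shape[0] else 0.0
    return assign, scatter(samples, assign, centers)


def fitness(chromosome: Chromosome | tuple, samples: np.ndarray) -> float:
    """φ(C) = 1 / (1 + δ²) of the forest grown from the chromosome's seeds."""
    seeds = chromosome.seed_ids if isinstance(chromosome, Chromosome) else tuple(chromosome)
    if len(set(seeds)) != len(seeds):
        raise StackValidationError("duplicate seed ids")
    samples = np.ascontiguousarray(samples, dtype=float)
    _, d2 = _forest_scatter(samples, np.asarray(seeds, dtype=np.int64))
    return 1.0 / (1.0 + d2)


def exhaustive_best_seeds(samples: np.ndarray, K: int) -> Chromosome:
    """Brute-force optimum over all K-subsets (small instances only)."""
    samples = np.ascontiguousarray(samples, dtype=float)
    best: Chromosome | None = None
    for combo in combinations(range(samples.shape[0]), K):
        phi = fitness(combo, samples)
        if best is None or phi > best.fitness:
            best = Chromosome(combo, phi)
    assert best is not None
    return best


def _repair(genes: list, pool: np.ndarray, rng: np.random.Generator) -> list:
    """Replace duplicate genes with uniformly random unused pool ids."""
    seen = set()
    dup_pos = []
    for pos, g in enumerate(genes):
        if g in seen:
            dup_pos.append(pos)
        seen.add(g)
    if dup_pos:
        unused = np.setdiff1d(pool, np.array(sorted(seen)))
        picks = rng.choice(unused, size=len(dup_pos), replace=False)
        for pos, g in zip(dup_pos, picks):
            genes[pos] = int(g)
    return genes


def ga_select_seeds(
    samples: np.ndarray,
    K: int,
    T: int = 800,
    crossover: float = 0.7,
    mutation: float = 0.001,
    tol: float = 1e-4,
    pop_size: int = 20,
    rng: np.random.Generator | int | None = None,
    objective=None,
    pool: np.ndarray | None = None,
    patience: int = 1,
    initial_population: list | None = None,
) -> Chromosome:
    """Evolve seed selections; returns the best chromosome ever seen.

    Termination: the best-so-far fitness improves by less than ``tol``
    for ``patience`` consecutive generations, or ``T`` generations elapse.
    The returned chromosome carries the best-so-far fitness trace in
    ``best_per_generation``.

    ``objective`` (default: :func:`fitness` on ``samples``) maps a gene
    tuple to a positive score; ``pool`` restricts the sample ids that may
    act as seeds; ``initial_population`` pre-seeds up to ``pop_size``
    chromosomes (the remainder is drawn uniformly from the pool).
    """
    samples = np.ascontiguousarray(samples, dtype=float)
    L = samples.shape[0]
    pool = np.arange(L) if pool is None else np.asarray(pool, dtype=int)
    if K > pool.size:
        raise StackValidationError(f"K={K} exceeds candidate pool size {pool.size}")
    if pop_size < 2:
        raise StackValidationError("population size must be >= 2")
    if not (0 <= crossover <= 1 and 0 <= mutation <= 1):
        raise StackValidationError("probabilities must lie in [0, 1]")
    if patience < 1:
        raise StackValidationError("patience must be >= 1")
    rng = np.random.default_rng(rng)
    if objective is None:
        objective = lambda genes: fitness(genes, samples)  # noqa: E731
    cache: dict[tuple, float] = {}

    def phi(genes) -> float:
        key = tuple(sorted(genes))
        if key not in cache:
            cache[key] = objective(tuple(genes))
        return cache[key]

    pop = [list(ind) for ind in (initial_population or [])][:pop_size]
    pop += [
        [int(g) for g in rng.choice(pool, size=K, replace=False)]
        for _ in range(pop_size - len(pop))
    ]
    best_genes, best_phi = None, -math.inf
    history: list[float] = []
    stagnant = 0
    for generation in range(T):
        fits = np.array([phi(ind) for ind in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_phi:
            best_phi = float(fits[gen_best])
            best_genes = list(pop[gen_best])
        history.append(best_phi)
        if generation > 0 and abs(history[-1] - history[-2]) < tol:
            stagnant += 1
            if stagnant >= patience:
                break
        else:
            stagnant = 0
        # roulette-wheel (fitness-proportional) selection; scores > 0
        probs = fits / fits.sum()
        chosen = rng.choice(pop_size, size=pop_size, p=probs)
        nxt = [list(pop[i]) for i in chosen]
        # single-point crossover on seed-id strings
        for j in range(0, pop_size - 1, 2):
            if K > 1 and rng.random() < crossover:
                point = int(rng.integers(1, K))
                a, b = nxt[j], nxt[j + 1]
                a[point:], b[point:] = b[point:], a[point:]
                nxt[j] = _repair(a, pool, rng)
                nxt[j + 1] = _repair(b, pool, rng)
        # per-gene mutation
        for ind in nxt:
            for pos in range(K):
                if rng.random() < mutation:
                    choices = np.setdiff1d(pool, np.array(ind))
                    ind[pos] = int(rng.choice(choices))
        pop = nxt
    assert best_genes is not None
    return Chromosome(tuple(best_genes), best_phi, best_per_generation=history)


def refine_seeds(
    genes,
    objective,
    pool: np.ndarray,
    rng: np.random.Generator,
    sweeps: int = 3,
    candidates: int = 12,
    strata: list[np.ndarray] | None = None,
) -> tuple[list, float]:
    """Gene-wise local refinement: greedily swap single seeds for better ones.

    A small memetic step after the GA; each position is offered
    ``candidates`` alternatives from the pool per sweep and keeps any
    strict improvement. When ``strata`` partition the pool, draws are
    spread across the strata so no part of feature space goes unprobed.
    """
    genes = [int(g) for g in genes]
    best = objective(tuple(genes))
    for _ in range(sweeps):
        improved = False
        for pos in range(len(genes)):
            if strata:
                per = max(1, -(-candidates // len(strata)))  # ceil
                picks = np.concatenate([
                    rng.choice(s, size=min(per, s.size), replace=False)
                    for s in strata if s.size
                ])
            else:
                picks = rng.choice(pool, size=min(candidates, pool.size), replace=False)
            for c in picks:
                if int(c) in genes:
                    continue
                trial = list(genes)
                trial[pos] = int(c)
                score = objective(tuple(trial))
                if score > best:
                    best, genes, improved = score, trial, True
        if not improved:
            break
    return genes, best


def _pool_strata(features: np.ndarray, pool: np.ndarray) -> dict[tuple, np.ndarray]:
    """Partition seed candidates by intensity tercile × lateral quartile."""
    l = features[pool, 0]
    x = features[pool, 3]
    l_edges = np.quantile(l, [1 / 3, 2 / 3])
    x_edges = np.quantile(x, [0.25, 0.5, 0.75])
    li = np.digitize(l, l_edges)
    xi = np.digitize(x, x_edges)
    strata = {}
    for a in range(3):
        for b in range(4):
            members = pool[(li == a) & (xi == b)]
            if members.size:
                strata[(a, b)] = members
    return strata


def _stratified_chromosome(strata, pool, rng: np.random.Generator) -> list:
    """A coverage-oriented chromosome: bright + peripheral-dark + two
    central-dark genes, matching the region model's expectations."""
    def draw(keys):
        arrays = [strata[k] for k in keys if k in strata]
        if not arrays:
            return int(rng.choice(pool))
        return int(rng.choice(arrays[int(rng.integers(len(arrays)))]))

    genes = [
        draw([(2, b) for b in range(4)]),          # brightest tercile
        draw([(0, 0), (0, 3), (1, 0), (1, 3)]),    # dark, lateral extremes
        draw([(0, 1), (1, 1)]),                    # dark, centre-left
        draw([(0, 2), (1, 2)]),                    # dark, centre-right
    ]
    return _repair(genes, pool, rng)


def normalize_features(features: np.ndarray) -> np.ndarray:
    """Min–max scale each attribute to [0, 1]; constant columns become 0."""
    features = np.asarray(features, dtype=float)
    lo = features.min(axis=0)
    span = features.max(axis=0) - lo
    span[span == 0] = 1.0
    return (features - lo) / span


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def make_model_consistency_objective(
    norm: np.ndarray,
    raw: np.ndarray,
    min_cluster: int | None = None,
    softness: float = 0.15,
):
    """Seed-selection objective: scatter fitness × anatomical plausibility.

    The scatter fitness φ alone cannot single out the anatomical
    partition: the chest wall and the extrathoracic area are ring- and
    frame-shaped, so their coordinate scatter stays large however they
    are clustered, and φ prefers splitting them over separating the two
    small, tight lung fields. The plausibility factor encodes the region
    model the identification stage assumes anyway (per-set grey value and
    coordinate statistics): the brightest set should be distinctly
    brighter than the rest (pleural tissue), and each of the two
    lung-candidate sets earns credit for being as dark as the
    extrathoracic set, more concentrated than it, and centred inside the
    thorax. Near-empty clusters are discounted.

    Returns ``objective(genes) -> score`` over gene tuples.
    """
    norm = np.ascontiguousarray(norm)
    raw = np.asarray(raw, dtype=float)
    L = raw.shape[0]
    if min_cluster is None:
        # the smallest legitimate cluster (a lung field) holds a few per
        # cent of the ROI superpixels; 1% is safely below that
        min_cluster = max(2, L // 100)
    gx, gy = raw[:, 3].mean(), raw[:, 4].mean()
    spread2 = float(np.mean((raw[:, 3] - gx) ** 2 + (raw[:, 4] - gy) ** 2)) + 1e-12

    def objective(genes: tuple) -> float:
        genes_arr = np.asarray(genes, dtype=np.int64)
        K = genes_arr.size
        assign = build_assignment(norm, genes_arr)
        phi = 1.0 / (1.0 + scatter(
            norm, assign,
            np.array([
                norm[assign == i].mean(axis=0) if np.any(assign == i) else np.zeros(norm.shape[1])
                for i in range(K)
            ]),
        ))
        sizes = np.bincount(assign, minlength=K)
        if sizes.min() == 0:
            return phi * 1e-3
        grey, var, cen = [], [], []
        for t in range(K):
            m = raw[assign == t]
            grey.append(float(np.mean(np.linalg.norm(m[:, :3], axis=1))))
            x0, y0 = m[:, 3].mean(), m[:, 4].mean()
            var.append(float(np.mean((m[:, 3] - x0) ** 2 + (m[:, 4] - y0) ** 2)))
            cen.append((x0, y0))
        pleural = int(np.argmax(grey))
        rest = [t for t in range(K) if t != pleural]
        extra = rest[int(np.argmax([var[t] for t in rest]))]
        lungs = [t for t in rest if t != extra]
        grange = grey[pleural] - min(grey) + 1e-9
        bright_margin = (grey[pleural] - max(grey[t] for t in rest)) / grange
        credit = 0.0
        for t in lungs:
            dark = 1.0 - abs(grey[t] - grey[extra]) / grange
            compact = (var[extra] - var[t]) / (var[extra] + var[t] + 1e-9)
            central = 1.0 - math.sqrt(
                ((cen[t][0] - cen[pleural][0]) ** 2 + (cen[t][1] - cen[pleural][1]) ** 2)
                / spread2
            )
            credit += (
                _sigmoid(dark / softness)
                * _sigmoid(compact / softness)
                * _sigmoid(central / softness)
            )
        score = phi * _sigmoid(bright_margin / softness) * (credit / max(len(lungs), 1))
        if len(lungs) == 2:
            # the lung fields flank the midline: their centroids must
            # straddle the pleural set's centroid in x
            xs = sorted(cen[t][0] for t in lungs)
            straddle = min(cen[pleural][0] - xs[0], xs[1] - cen[pleural][0])
            score *= _sigmoid(straddle / math.sqrt(spread2) / softness)
        score *= min(1.0, sizes.min() / min_cluster)
        return score

    return objective


def cluster_superpixels(
    spmap,
    K: int = 4,
    T: int = 800,
    crossover: float = 0.7,
    mutation: float = 0.001,
    tol: float = 1e-4,
    pop_size: int = 20,
    rng: np.random.Generator | int | None = None,
    coord_scale: float = 0.25,
    patience: int = 10,
    refine_sweeps: int = 3,
    refine_candidates: int = 20,
    seed_depth: int = 2,
) -> list[np.ndarray]:
    """GA seed selection + forest build over a SuperpixelMap's features.

    Attributes are min–max scaled, with coordinates compressed to
    ``[0, coord_scale]`` so grey level stays the primary grouping cue and
    coordinates disambiguate equal-intensity structures. Seed candidates
    are drawn from the leading ``seed_depth`` slices — trees must be
    anchored before the samples they collect arrive, mirroring the
    slice-0 initialisation of the superpixel stage. The GA maximises the model-consistency
    objective and its best chromosome gets a gene-wise local refinement.

    Returns K arrays of superpixel ids (a partition of all superpixels).
    """
    features = np.asarray(spmap.features if hasattr(spmap, "features") else spmap, dtype=float)
    if features.shape[0] == 0:
        raise StackValidationError("no superpixel features to cluster")
    norm = normalize_features(features)
    norm[:, 3:] *= coord_scale
    norm = np.ascontiguousarray(norm)
    rng = np.random.default_rng(rng)
    zmin = features[:, 5].min()
    pool = np.nonzero(features[:, 5] < zmin + seed_depth)[0]
    if pool.size < K:
        pool = np.arange(features.shape[0])
    objective = make_model_consistency_objective(norm, features)
    cache: dict[tuple, float] = {}

    def cached(genes: tuple) -> float:
        key = tuple(sorted(genes))
        if key not in cache:
            cache[key] = objective(genes)
        return cache[key]

    strata = _pool_strata(features, pool)
    init = None
    if K == 4:
        # half the initial population encodes the coverage heuristic
        init = [
            _stratified_chromosome(strata, pool, rng)
            for _ in range(pop_size // 2)
        ]
    best = ga_select_seeds(
        norm, K, T=T, crossover=crossover, mutation=mutation,
        tol=tol, pop_size=pop_size, rng=rng,
        objective=cached, pool=pool, patience=patience,
        initial_population=init,
    )
    genes, _ = refine_seeds(
        best.seed_ids, cached, pool, rng,
        sweeps=refine_sweeps, candidates=refine_candidates,
        strata=list(strata.values()),
    )
    assign = build_assignment(norm, np.asarray(genes, dtype=np.int64))
    return [np.nonzero(assign == i)[0] for i in range(K)]
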