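"""Synthetic benchmark generator.

Emulates the benchmark design used to validate the model: a random
multifurcating tree of depth 5 over ``p`` features; per-feature base
log-abundances drawn Unif(-2, 2); ground-truth effects placed on one
internal node directly above the leaves plus two leaves (their joint leaf
set ``p'`` is differentially abundant, and never includes the last feature,
which serves as the reference); and per-sample counts drawn from a
Dirichlet-Multinomial at a fixed sequencing depth of 10,000 whose
concentration vector is rescaled to a total of ``(1 - psi) / psi`` with
overdispersion ``psi = 0.002``.

The control group uses concentrations ``exp(alpha)``; the treatment group
``exp(alpha + beta)`` on the affected components.  An optional second
covariate ``x1 ~ Unif(0, 1)`` contributes ``beta1 * x1`` on its own target
node's leaves, and a root-level variant is expressed by passing an explicit
high-level node as ground truth.  The full factorial benchmark grid is
``p in (10, 30, 50, 100) x n0 in (5, 20, 30, 50) x beta in (0.3, 0.5, 0.7,
0.9) x 20 replicates`` = 1280 datasets, with one tree per ``p`` reused
across that size's cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CompositionalDataset, preprocess
from .trees import Hierarchy, _Node


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset draw."""

    p: int
    depth: int = 5
    n0: int = 5
    n1: int | None = None
    effect_size: float = 0.5
    total: int = 10000
    psi: float = 0.002
    seed: int | None = None
    second_covariate: tuple | None = None  # (effect_size, node_name)

    def __post_init__(self):
        if not (0.0 < self.psi < 1.0):
            raise ValueError("psi must lie in (0, 1)")
        if self.n1 is None:
            self.n1 = self.n0


@dataclass
class GroundTruth:
    """Ground-truth effect placement for one covariate set.

    ``affected_nodes`` maps covariate index to the node names carrying a
    true effect; ``affected_leaves`` is each covariate's induced leaf set
    ``p'`` (union of the affected nodes' subtree leaves).  ``labels`` are
    the per-feature binary differential-abundance labels of covariate 0.
    """

    affected_nodes: dict
    affected_leaves: dict
    labels: np.ndarray
    feature_names: list = field(default_factory=list)

    @classmethod
    def from_nodes(cls, tree: Hierarchy, nodes_by_covariate: dict) -> "GroundTruth":
        names = tree.leaf_names
        leaves = {
            l: sorted(
                {lf for nd in nds for lf in tree.subtree_leaves(nd)},
                key=names.index,
            )
            for l, nds in nodes_by_covariate.items()
        }
        labels = np.isin(names, leaves.get(0, [])).astype(int)
        return cls(
            affected_nodes=nodes_by_covariate,
            affected_leaves=leaves,
            labels=labels,
            feature_names=names,
        )


@dataclass
class SimulatedDataset:
    """One generated dataset: raw integer counts + covariates + labels."""

    id: str
    Y: np.ndarray  # raw integer counts, n x p
    X: np.ndarray  # n x d
    feature_names: list
    covariate_names: list
    truth: GroundTruth
    spec: SimulationSpec

    def to_dataset(self) -> CompositionalDataset:
        """Preprocessed view (pseudo-counts, covariate scaling)."""
        return preprocess(
            self.Y,
            self.X,
            feature_names=self.feature_names,
            covariate_names=self.covariate_names,
        )


def random_multifurcating_tree(p: int, depth: int = 5, seed=None) -> Hierarchy:
    """Generate a seeded random multifurcating tree with exact given depth.

    Construction: the leaf index set is recursively partitioned into a
    random number (2-4) of non-empty blocks per level; one designated block
    per level is kept large enough to realise the target depth exactly, and
    at the last level blocks fan out into leaves.  Leaves are named ``T1 ...
    Tp`` in left-to-right order.  Retries (bounded) ensure at least one
    internal node has more than two children.
    """
    if p < 4 or depth < 2:
        raise ValueError("need p >= 4 and depth >= 2")
    if p < depth + 1:
        raise ValueError(f"p={p} too small to realise depth {depth} (need p >= depth+1)")
    rng = np.random.default_rng(seed)

    def split_sizes(m, k, min_first):
        # composition of m into k positive parts, part 0 >= min_first
        extra = m - min_first - (k - 1)
        alloc = rng.multinomial(extra, np.full(k, 1.0 / k)) if extra > 0 else np.zeros(k, int)
        sizes = alloc + 1
        sizes[0] += min_first - 1
        return sizes

    def grow_max(m, r):
        if m == 1:
            return _Node()
        if r == 1:
            return _Node(children=[_Node() for _ in range(m)])
        k = int(rng.integers(2, min(4, m) + 1))
        sizes = split_sizes(m, k, 1)
        return _Node(children=[grow_max(int(s), r - 1) for s in sizes])

    def grow_exact(m, r):
        if r == 0:
            return _Node()
        if r == 1:
            return _Node(children=[_Node() for _ in range(m)])
        k = int(rng.integers(2, min(4, m - r + 1) + 1))
        sizes = split_sizes(m, k, r)
        children = [grow_exact(int(sizes[0]), r - 1)]
        children += [grow_max(int(s), r - 1) for s in sizes[1:]]
        order = rng.permutation(len(children))
        return _Node(children=[children[i] for i in order])

    for _ in range(100):
        root = grow_exact(p, depth)
        # name leaves left-to-right
        idx = 0

        def name_leaves(node):
            nonlocal idx
            if node.is_leaf:
                idx += 1
                node.name = f"T{idx}"
            else:
                for c in node.children:
                    name_leaves(c)

        name_leaves(root)
        tree = Hierarchy(root)
        if tree.depth == depth and any(
            len(n.children) > 2 for n in tree.internal_nodes
        ):
            return tree
        idx = 0
    raise RuntimeError("failed to generate a suitable tree (increase p or depth)")


def choose_effect_nodes(tree: Hierarchy, seed=None) -> GroundTruth:
    """Pick the benchmark's three true-effect nodes.

    One internal node whose children are all leaves, plus two leaves;
    subtrees are mutually disjoint and never cover the last feature (the
    designated reference).
    """
    rng = np.random.default_rng(seed)
    names = tree.leaf_names
    reference = names[-1]
    candidates = [
        n.name
        for n in tree.internal_nodes
        if all(c.is_leaf for c in n.children)
        and reference not in tree.subtree_leaves(n.name)
    ]
    if not candidates:
        raise ValueError("tree has no internal node with leaf-only children away from the reference")
    internal = candidates[rng.integers(len(candidates))]
    covered = set(tree.subtree_leaves(internal)) | {reference}
    free_leaves = [nm for nm in names if nm not in covered]
    if len(free_leaves) < 2:
        raise ValueError("not enough free leaves to place two leaf effects")
    pick = rng.choice(len(free_leaves), size=2, replace=False)
    leaves = [free_leaves[i] for i in sorted(pick)]
    return GroundTruth.from_nodes(tree, {0: [internal] + leaves})


def simulate_dataset(
    spec: SimulationSpec, truth: GroundTruth, tree: Hierarchy, dataset_id: str = "sim"
) -> SimulatedDataset:
    """Draw one dataset under the benchmark's generative process.

    One base log-abundance vector ``alpha ~ Unif(-2, 2)`` is drawn per
    dataset and shared by all samples; each sample's concentration is
    ``exp(alpha + sum_l x_il * beta_l * 1(p'_l))``, rescaled to total
    ``(1 - psi) / psi``, and counts are a Dirichlet-Multinomial draw at the
    fixed depth ``spec.total``.
    """
    rng = np.random.default_rng(spec.seed)
    names = tree.leaf_names
    p = len(names)
    n = spec.n0 + spec.n1

    alpha = rng.uniform(-2.0, 2.0, size=p)

    group = np.concatenate([np.zeros(spec.n0), np.ones(spec.n1)])
    X_cols = [group]
    covariate_names = ["condition"]
    effects = [spec.effect_size * truth.labels.astype(float)]

    truth_out = truth
    if spec.second_covariate is not None:
        beta1, node_name = spec.second_covariate
        leaves1 = tree.subtree_leaves(node_name)
        ind1 = np.isin(names, leaves1).astype(float)
        X_cols.append(rng.uniform(0.0, 1.0, size=n))
        covariate_names.append("x1")
        effects.append(beta1 * ind1)
        nodes = dict(truth.affected_nodes)
        nodes[1] = [node_name]
        truth_out = GroundTruth.from_nodes(tree, nodes)

    X = np.column_stack(X_cols)
    B = np.vstack(effects)  # d x p

    target_sum = (1.0 - spec.psi) / spec.psi
    log_gamma = alpha[None, :] + X @ B
    gamma = np.exp(log_gamma)
    gamma_star = gamma / gamma.sum(axis=1, keepdims=True) * target_sum

    Y = np.empty((n, p), dtype=np.int64)
    for i in range(n):
        pi = rng.dirichlet(gamma_star[i])
        Y[i] = rng.multinomial(spec.total, pi)

    return SimulatedDataset(
        id=dataset_id,
        Y=Y,
        X=X,
        feature_names=names,
        covariate_names=covariate_names,
        truth=truth_out,
        spec=spec,
    )


def benchmark_grid(
    p_values=(10, 30, 50, 100),
    n0_values=(5, 20, 30, 50),
    effect_sizes=(0.3, 0.5, 0.7, 0.9),
    replicates: int = 20,
    depth: int = 5,
    total: int = 10000,
    psi: float = 0.002,
    seed: int = 0,
):
    """Yield the full factorial benchmark: (tree, truth, SimulatedDataset).

    One tree (and one ground-truth node choice) per value of ``p``, reused
    across all of that size's cells; dataset IDs deterministically encode
    (p, n0, beta, replicate); everything reproduces bit-exactly from the
    master seed.
    """
    ss = np.random.SeedSequence(seed)
    tree_seeds = ss.spawn(len(p_values))
    trees = {}
    truths = {}
    for pv, tseed in zip(p_values, tree_seeds):
        sub = tseed.spawn(2)
        trees[pv] = random_multifurcating_tree(pv, depth=depth, seed=sub[0])
        truths[pv] = choose_effect_nodes(trees[pv], seed=sub[1])
    data_ss = ss.spawn(1)[0]
    cell_seeds = data_ss.spawn(len(p_values) * len(n0_values) * len(effect_sizes) * replicates)
    i = 0
    for pv in p_values:
        for n0 in n0_values:
            for beta in effect_sizes:
                for rep in range(replicates):
                    spec = SimulationSpec(
                        p=pv,
                        depth=depth,
                        n0=n0,
                        n1=n0,
                        effect_size=beta,
                        total=total,
                        psi=psi,
                        seed=cell_seeds[i],
                    )
                    ds_id = f"p{pv}_n{n0}_b{beta}_r{rep}"
                    yield trees[pv], truths[pv], simulate_dataset(
                        spec, truths[pv], trees[pv], dataset_id=ds_id
                    )
                    i += 1


def export_dataset(sim: SimulatedDataset, tree: Hierarchy, out_dir) -> dict:
    """Write counts CSV, covariates CSV, newick, and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = out / f"{sim.id}_counts.csv"
    covs = out / f"{sim.id}_covariates.csv"
    nwk = out / f"{sim.id}_tree.nwk"
    gt = out / f"{sim.id}_truth.json"
    pd.DataFrame(sim.Y, columns=sim.feature_names).to_csv(counts, index_label="sample")
    pd.DataFrame(sim.X, columns=sim.covariate_names).to_csv(covs, index_label="sample")
    nwk.write_text(tree.to_newick() + "\n")
    gt.write_text(
        json.dumps(
            {
                "affected_nodes": {str(k): v for k, v in sim.truth.affected_nodes.items()},
                "affected_leaves": {str(k): v for k, v in sim.truth.affected_leaves.items()},
                "labels": sim.truth.labels.tolist(),
            },
            indent=2,
        )
    )
    return {"counts": str(counts), "covariates": str(covs), "tree": str(nwk), "truth": str(gt)}
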