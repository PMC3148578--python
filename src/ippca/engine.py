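"""The iterative pruning loop.

Starting from the full panel, each group of individuals is re-encoded from
raw calls (allele frequencies, centering, normalization, spectrum and the
variance-fraction rank p are all recomputed within the group -- never sliced
from a parent matrix, because the normalization is frequency dependent), the
stopping criterion is evaluated, and a structured group is bisected by
2-means on its leading principal-component projections.  Recursion continues
until every terminal group is declared homogeneous or a guard fires
(minimum size, maximum depth, degenerate projections).  Leaves are named
SP1..SPK in depth-first discovery order, the left child at each split being
the cluster containing the lowest original index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans

from ippca.criteria import (
    DEFAULT_EIGENDEV_THRESHOLD,
    DEFAULT_TW_ALPHA,
    StructureDecision,
    decide_eigendev,
    decide_tw,
    eigendev,
    tw_test,
)
from ippca.exceptions import CriterionError, IppcaError, NoVariationError, UsageError
from ippca.genotype_io import GenotypeTable, encode_table
from ippca.spectral import covariance, eigendecompose, select_rank

logger = logging.getLogger("ippca.engine")

__all__ = [
    "IppcaConfig",
    "SplitNode",
    "SubpopulationTree",
    "ComparisonReport",
    "bisect",
    "run_ippca",
    "compare_criteria",
]


@dataclass
class IppcaConfig:
    """Engine parameters; defaults are the package's documented operating point."""

    criterion: str = "eigendev"  # 'eigendev' | 'tw'
    threshold: float = DEFAULT_EIGENDEV_THRESHOLD
    tw_alpha: float = DEFAULT_TW_ALPHA
    dims: int = 2  # projection dimensions fed to the bisecting clustering
    n_min: int = 20  # groups below this close as leaves (criteria unreliable)
    max_depth: int = 25  # runaway-recursion fuse
    variance_fraction: float = 0.90
    seed: int = 0
    kmeans_restarts: int = 10

    def validate(self) -> None:
        if self.criterion not in ("eigendev", "tw"):
            raise UsageError(f"unknown criterion '{self.criterion}'")
        if self.dims < 1:
            raise UsageError("dims must be >= 1")
        if self.n_min < 2:
            raise UsageError("n_min must be >= 2")


@dataclass
class SplitNode:
    member_indices: np.ndarray  # original (root-level) indices, ascending
    depth: int
    decision: Optional[StructureDecision] = None
    children: list["SplitNode"] = field(default_factory=list)
    leaf_label: Optional[str] = None
    guard: Optional[str] = None  # reason a leaf closed without a homogeneous verdict

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_dict(self) -> dict:
        d: dict = {
            "size": int(len(self.member_indices)),
            "depth": self.depth,
            "guard": self.guard,
            "leaf_label": self.leaf_label,
        }
        if self.decision is not None:
            dec = self.decision
            d["decision"] = {
                "criterion": dec.criterion,
                "statistic": dec.statistic,
                "threshold": dec.threshold,
                "p_used": dec.p_used,
                "verdict": dec.verdict,
                "radicand_flag": dec.radicand_flag,
                "p_value": dec.p_value,
            }
        if self.is_leaf:
            d["member_indices"] = [int(i) for i in self.member_indices]
        else:
            d["children"] = [c.to_dict() for c in self.children]
        return d


@dataclass
class SubpopulationTree:
    """Binary split tree whose leaves are the terminal subpopulations."""

    root: SplitNode
    individual_ids: list[str]

    def leaves(self) -> list[SplitNode]:
        out: list[SplitNode] = []

        def walk(node: SplitNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    @property
    def K(self) -> int:
        return len(self.leaves())

    @property
    def assignment(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for leaf in self.leaves():
            for i in leaf.member_indices:
                out[self.individual_ids[int(i)]] = leaf.leaf_label
        return out

    def to_dict(self) -> dict:
        return {
            "individual_ids": self.individual_ids,
            "K": self.K,
            "tree": self.root.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @staticmethod
    def leaf_members_from_json(path) -> dict[str, list[str]]:
        """Leaf label -> individual ids, read back from a tree.json dump."""
        with open(path) as fh:
            d = json.load(fh)
        ids = d["individual_ids"]
        out: dict[str, list[str]] = {}

        def walk(node: dict) -> None:
            if "children" in node:
                for c in node["children"]:
                    walk(c)
            else:
                out[node["leaf_label"]] = [ids[i] for i in node["member_indices"]]

        walk(d["tree"])
        return out


def bisect(projections: np.ndarray, seed: int, restarts: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Split points into two non-empty clusters by 2-means on PC coordinates.

    Returns (left, right) local index arrays in ascending order; the left
    cluster is canonically the one containing the lowest local index.
    Raises CriterionError when all points coincide.
    """
    pts = np.asarray(projections, dtype=np.float64)
    if pts.ndim == 1:
        pts = pts[:, None]
    if len(pts) < 2:
        raise CriterionError("cannot bisect fewer than 2 points")
    if np.allclose(pts, pts[0], atol=0.0):
        raise CriterionError("cannot bisect: all projected points identical")
    km = KMeans(n_clusters=2, n_init=restarts, random_state=seed % (2**32))
    lab = km.fit_predict(pts)
    left_cluster = lab[0]  # cluster containing the lowest local index
    left = np.flatnonzero(lab == left_cluster)
    right = np.flatnonzero(lab != left_cluster)
    if len(left) == 0 or len(right) == 0:
        raise CriterionError("degenerate bisection: empty cluster")
    return left, right


def _node_decision(
    table: GenotypeTable, config: IppcaConfig
) -> tuple[Optional[StructureDecision], Optional[np.ndarray], Optional[str]]:
    """Evaluate the stopping criterion on a group.

    Returns (decision, projections, guard); guard is non-None when the
    criterion could not run and the node must close as a leaf.
    """
    enc = encode_table(table)
    spectrum_input_dead = not np.any(enc.values)
    if spectrum_input_dead:
        return None, None, "no_variation"
    spectrum = eigendecompose(covariance(enc))
    try:
        rank = select_rank(spectrum, config.variance_fraction, m=enc.m, n=enc.n)
    except NoVariationError:
        return None, None, "no_variation"
    try:
        if config.criterion == "eigendev":
            value, fit = eigendev(spectrum, rank)
            decision = decide_eigendev(
                value, config.threshold, p_used=fit.p_used, radicand_flag=fit.radicand_adjusted
            )
        else:
            stat, p_value = tw_test(spectrum, enc.m, enc.n)
            decision = decide_tw(stat, p_value, config.tw_alpha)
    except CriterionError as exc:
        logger.info("criterion_error=%r", str(exc))
        return None, None, "criterion_error"
    return decision, spectrum.projections, None


def run_ippca(table: GenotypeTable, config: Optional[IppcaConfig] = None) -> SubpopulationTree:
    """Resolve the subpopulation tree of a genotype table.

    Depth-first recursion; deterministic given ``config.seed``.  One log line
    is emitted per node (size, statistic, verdict/guard).
    """
    config = config or IppcaConfig()
    config.validate()
    m = table.n_individuals
    if m < 2:
        raise IppcaError("need at least 2 individuals")
    counter = [0]

    def node_seed() -> int:
        counter[0] += 1
        return (config.seed * 1_000_003 + counter[0]) % (2**31)

    def build(indices: np.ndarray, depth: int) -> SplitNode:
        node = SplitNode(member_indices=indices, depth=depth)
        size = len(indices)
        if size < config.n_min:
            node.guard = "min_size"
            logger.info("node depth=%d size=%d guard=min_size", depth, size)
            return node
        sub = table.subset(indices)
        decision, projections, guard = _node_decision(sub, config)
        node.decision = decision
        if guard is not None:
            node.guard = guard
            logger.info("node depth=%d size=%d guard=%s", depth, size, guard)
            return node
        logger.info(
            "node depth=%d size=%d criterion=%s statistic=%.6g verdict=%s",
            depth, size, decision.criterion, decision.statistic, decision.verdict,
        )
        if decision.verdict == "homogeneous":
            return node
        if depth >= config.max_depth:
            node.guard = "max_depth"
            logger.info("node depth=%d size=%d guard=max_depth", depth, size)
            return node
        d = min(config.dims, projections.shape[1])
        try:
            left, right = bisect(projections[:, :d], node_seed(), config.kmeans_restarts)
        except CriterionError:
            node.guard = "degenerate"
            logger.info("node depth=%d size=%d guard=degenerate", depth, size)
            return node
        node.children = [build(indices[left], depth + 1), build(indices[right], depth + 1)]
        return node

    root = build(np.arange(m), 0)
    tree = SubpopulationTree(root=root, individual_ids=list(table.individual_ids))
    for k, leaf in enumerate(tree.leaves(), start=1):
        leaf.leaf_label = f"SP{k}"
    logger.info("done K=%d", tree.K)
    return tree


@dataclass
class ComparisonReport:
    eigendev_tree: SubpopulationTree
    tw_tree: SubpopulationTree
    k_eigendev: int
    k_tw: int
    refinement_score: float  # fraction of TW leaves wholly inside one EigenDev leaf


def compare_criteria(table: GenotypeTable, config: Optional[IppcaConfig] = None) -> ComparisonReport:
    """Run both stopping criteria on identical input and seeds.

    The refinement score is the fraction of TW leaves whose members all fall
    inside a single EigenDev leaf (1.0 when TW strictly refines EigenDev).
    """
    config = config or IppcaConfig()
    cfg_e = IppcaConfig(**{**config.__dict__, "criterion": "eigendev"})
    cfg_t = IppcaConfig(**{**config.__dict__, "criterion": "tw"})
    tree_e = run_ippca(table, cfg_e)
    tree_t = run_ippca(table, cfg_t)
    eig_leaf_of = {}
    for leaf in tree_e.leaves():
        for i in leaf.member_indices:
            eig_leaf_of[int(i)] = leaf.leaf_label
    tw_leaves = tree_t.leaves()
    nested = sum(
        1 for leaf in tw_leaves if len({eig_leaf_of[int(i)] for i in leaf.member_indices}) == 1
    )
    return ComparisonReport(
        eigendev_tree=tree_e,
        tw_tree=tree_t,
        k_eigendev=tree_e.K,
        k_tw=tree_t.K,
        refinement_score=nested / len(tw_leaves),
    )
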