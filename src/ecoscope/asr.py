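"""Two-state maximum-likelihood ancestral state reconstruction.

A binary habitat trait (state 1 = oxic, 2 = anoxic) evolves along a rooted
phylogeny under a continuous-time Markov chain with rates q12 and q21; the
transition matrix over a branch of length t has the closed form

    P(t) = Pi + exp(-(q12 + q21) t) (I - Pi),   Pi = rows of (pi1, pi2),

with stationary frequencies pi = (q21, q12) / (q12 + q21).  Likelihoods use
Felsenstein pruning with per-node scaling; marginal node posteriors combine
the subtree partials with the rest-of-tree likelihood via a preorder pass
(the re-rooting formulation).  The root prior defaults to the stationary
distribution; a flat prior is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .tables_io import AbundanceTable, Phylogeny, SampleMetadata
from .synthetic_data import transition_matrix

__all__ = [
    "MkModel",
    "AsrResult",
    "prune_loglik",
    "fit_rates",
    "marginal_asr",
    "states_from_metadata",
]

_MIN_BRANCH = 1e-9  # floor for zero-length branches


@dataclass(frozen=True)
class MkModel:
    """Two-state Markov model; ``equal_rates`` records the constraint used in fitting."""

    q12: float
    q21: float
    equal_rates: bool = False

    def __post_init__(self):
        if self.q12 < 0 or self.q21 < 0 or (self.q12 == 0 and self.q21 == 0):
            raise ValueError("rates must be non-negative with at least one positive")

    def stationary(self) -> np.ndarray:
        q = self.q12 + self.q21
        return np.array([self.q21 / q, self.q12 / q])

    def transition(self, t: float) -> np.ndarray:
        return transition_matrix(self.q12, self.q21, max(t, _MIN_BRANCH))


def _root_prior(model: MkModel, root_prior: str) -> np.ndarray:
    if root_prior == "stationary":
        return model.stationary()
    if root_prior == "flat":
        return np.array([0.5, 0.5])
    raise ValueError(f"unknown root prior {root_prior!r}")


def _check_states(tree: Phylogeny, tip_states: dict) -> None:
    for leaf in tree.leaf_node_iter():
        s = tip_states.get(leaf.taxon.label)
        if s not in (1, 2):
            raise ValueError(
                f"tip {leaf.taxon.label!r} has missing or invalid state {s!r}"
            )


def _partials(tree: Phylogeny, tip_states: dict, model: MkModel):
    """Postorder conditional likelihoods with per-node log scaling."""
    down = {}
    log_scale = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.zeros(2)
            vec[tip_states[node.taxon.label] - 1] = 1.0
            down[node] = vec
            log_scale[node] = 0.0
            continue
        vec = np.ones(2)
        scale = 0.0
        for child in node.child_nodes():
            P = model.transition(child.edge.length or 0.0)
            vec = vec * (P @ down[child])
            scale += log_scale[child]
        m = vec.max()
        if m <= 0:
            raise ValueError("zero likelihood; inconsistent data")
        down[node] = vec / m
        log_scale[node] = scale + np.log(m)
    return down, log_scale


def prune_loglik(
    tree: Phylogeny, tip_states: dict, model: MkModel, root_prior: str = "stationary"
) -> float:
    """Exact log-likelihood of the tip states under the 2-state CTMC."""
    _check_states(tree, tip_states)
    down, log_scale = _partials(tree, tip_states, model)
    root = tree.seed_node
    pi = _root_prior(model, root_prior)
    return float(np.log(pi @ down[root]) + log_scale[root])


def fit_rates(
    tree: Phylogeny,
    tip_states: dict,
    equal_rates: bool = True,
    root_prior: str = "stationary",
    rate_bounds: tuple = (1e-6, 1e3),
) -> MkModel:
    """Maximum-likelihood transition rates by bounded numerical optimisation.

    Convergence tolerance is 1e-8 on the log-likelihood scale.  When one
    state is absent from the tips the corresponding rate is driven toward
    its lower bound and a boundary warning is raised.
    """
    _check_states(tree, tip_states)
    if len(tip_states) < 4:
        raise ValueError("rate fitting needs at least 4 tips")
    states = set(tip_states.values())
    if len(states) < 2:
        warnings.warn(
            "only one tip state observed; the unused rate is a boundary estimate"
        )
    lo, hi = np.log(rate_bounds[0]), np.log(rate_bounds[1])

    if equal_rates:
        def nll(logq):
            q = float(np.exp(logq))
            return -prune_loglik(tree, tip_states, MkModel(q, q, True), root_prior)

        res = optimize.minimize_scalar(
            nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
        )
        q = float(np.exp(res.x))
        return MkModel(q, q, equal_rates=True)

    def nll(logqs):
        q12, q21 = np.exp(logqs)
        return -prune_loglik(tree, tip_states, MkModel(q12, q21, False), root_prior)

    best = None
    for start in ([0.0, 0.0], [np.log(0.1)] * 2, [np.log(2.0)] * 2):
        res = optimize.minimize(
            nll, x0=np.array(start), method="L-BFGS-B",
            bounds=[(lo, hi), (lo, hi)], options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    q12, q21 = np.exp(best.x)
    return MkModel(float(q12), float(q21), equal_rates=False)


@dataclass(frozen=True)
class AsrResult:
    probabilities: pd.DataFrame  # index node label; columns p_oxic (state 1), p_anoxic (state 2)
    log_likelihood: float
    model: MkModel


def _label_nodes(tree: Phylogeny) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            i += 1
            node.label = f"node{i}"


def marginal_asr(
    tree: Phylogeny, tip_states: dict, model: MkModel, root_prior: str = "stationary"
) -> AsrResult:
    """Marginal posterior state probabilities at every internal node.

    For node v, P(state) combines the below-v partial likelihood with the
    likelihood of the rest of the tree computed by a preorder pass; the two
    state probabilities sum to 1 at each node, and at the root they
    integrate to the pruning likelihood.
    """
    _check_states(tree, tip_states)
    _label_nodes(tree)
    down, log_scale = _partials(tree, tip_states, model)
    root = tree.seed_node
    pi = _root_prior(model, root_prior)
    loglik = float(np.log(pi @ down[root]) + log_scale[root])

    up = {root: pi.copy()}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        for child in node.child_nodes():
            sib = np.ones(2)
            for other in node.child_nodes():
                if other is child:
                    continue
                P = model.transition(other.edge.length or 0.0)
                sib = sib * (P @ down[other])
            msg = up[node] * sib
            P = model.transition(child.edge.length or 0.0)
            vec = msg @ P  # sum_i up_i * P[i, j]
            m = vec.max()
            up[child] = vec / m if m > 0 else vec

    rows = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        joint = up[node] * down[node]
        total = joint.sum()
        if total <= 0:
            raise ValueError("zero marginal likelihood at an internal node")
        rows[node.label] = joint / total
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["p_oxic", "p_anoxic"])
    return AsrResult(probabilities=df, log_likelihood=loglik, model=model)


def states_from_metadata(
    table: AbundanceTable, metadata: SampleMetadata
) -> dict:
    """Assign each taxon a binary oxic state by majority over occupied libraries.

    State 1 = oxic, 2 = anoxic; ties break toward anoxic with a warning.
    Taxa present nowhere are omitted.
    """
    metadata.require_libraries(table.libraries)
    oxic = (metadata.data.loc[list(table.libraries), "oxic_status"] == "oxic").to_numpy()
    states = {}
    ties = []
    present = table.values > 0
    for j, taxon in enumerate(table.taxa):
        occ = present[:, j]
        if not occ.any():
            continue
        n_oxic = int(np.sum(occ & oxic))
        n_anoxic = int(occ.sum()) - n_oxic
        if n_oxic == n_anoxic:
            ties.append(taxon)
            states[taxon] = 2
        else:
            states[taxon] = 1 if n_oxic > n_anoxic else 2
    if ties:
        warnings.warn(f"{len(ties)} taxa tied oxic/anoxic; assigned anoxic")
    return states
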