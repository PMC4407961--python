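"""BM/OU trait-evolution models on a rooted phylogeny and ancestral reconstruction.

The model layer treats tip trait values as one draw from a multivariate normal
whose covariance is induced by the tree:

* **Brownian motion (BM)**: ``cov(i, j) = sigma2 * s_ij`` where ``s_ij`` is the
  depth (root-to-node path length) of the MRCA of tips i and j.
* **Ornstein–Uhlenbeck (OU)**, root-conditioned with the root at the process
  optimum: for tips at depths ``t_i``, ``t_j`` with MRCA depth ``s_ij``,

  ``cov(i, j) = sigma2/(2*alpha) * exp(-alpha*(t_i + t_j - 2*s_ij)) * (1 - exp(-2*alpha*s_ij))``

  This parameterization nests BM exactly as ``alpha -> 0``, so the AIC
  comparison (k = 2 for BM, k = 3 for OU) is between nested models.

Maximum likelihood is analytic in the root state (GLS) and the rate ``sigma2``
for a fixed ``alpha``; the OU fit profiles the likelihood over ``log(alpha)`` on
a deterministic grid followed by bounded refinement. Ancestral states at the
MRCA of a designated sister pair are the conditional mean/SD of the node state
given all tips under the fitted model — reconstruction is deliberately
restricted to first-level MRCAs because its accuracy decays toward the root.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .errors import CavepairsError, SingularCovarianceError, TreeError

LOG_ALPHA_GRID = np.linspace(np.log(1e-6), np.log(1e2), 33)

ANCESTRAL_VARIANTS = ("lower", "mean", "upper")


class Phylogeny:
    """Rooted tree with mandatory branch lengths, indexed for covariance work.

    Exposes tip labels in a fixed order, tip depths ``t`` and the MRCA-depth
    matrix ``S`` (``S[i, j]`` = depth of the MRCA of tips i and j, ``S[i, i]`` =
    depth of tip i), which together determine every Gaussian model used here.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._index()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                rooting="force-rooted",
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"could not parse newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        out = io.StringIO()
        self._tree.write(
            file=out, schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        return out.getvalue().strip()

    def _index(self) -> None:
        tree = self._tree
        leaves = tree.leaf_node_iter()
        labels = []
        for lf in leaves:
            if lf.taxon is None or lf.taxon.label is None:
                raise TreeError("unlabeled tip in tree")
            labels.append(lf.taxon.label)
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        if len(labels) < 2:
            raise TreeError("tree must have at least 2 tips")

        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                nd.depth = 0.0
                continue
            if nd.edge.length is None:
                raise TreeError("branch lengths required on every non-root edge")
            if nd.edge.length < 0:
                raise TreeError("negative branch length")
            nd.depth = nd.parent_node.depth + float(nd.edge.length)

        self.tip_labels: list[str] = []
        index: dict[str, int] = {}
        for lf in tree.leaf_node_iter():
            index[lf.taxon.label] = len(self.tip_labels)
            self.tip_labels.append(lf.taxon.label)
        self._tip_index = index

        n = len(self.tip_labels)
        depths = np.zeros(n)
        S = np.zeros((n, n))
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                i = index[nd.taxon.label]
                nd.tip_indices = (i,)
                depths[i] = nd.depth
                S[i, i] = nd.depth
            else:
                groups = [ch.tip_indices for ch in nd.child_nodes()]
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        ia = np.array(groups[a])
                        ib = np.array(groups[b])
                        S[np.ix_(ia, ib)] = nd.depth
                        S[np.ix_(ib, ia)] = nd.depth
                nd.tip_indices = tuple(i for g in groups for i in g)
        if np.any(depths <= 0):
            zero = [self.tip_labels[i] for i in np.nonzero(depths <= 0)[0]]
            raise TreeError(f"zero-length root-to-tip path for tips {zero}")
        self.tip_depths = depths
        self.mrca_depths = S

    # -- queries -------------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        return bool(np.ptp(self.tip_depths) <= tol)

    def prune_to(self, keep: Sequence[str], warn: bool = True) -> "Phylogeny":
        """Drop tips not in ``keep``; logs which tips were removed."""
        keep_set = set(keep)
        missing = keep_set - set(self.tip_labels)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        drop = [l for l in self.tip_labels if l not in keep_set]
        if not drop:
            return self
        if warn:
            warnings.warn(f"pruning {len(drop)} tips without trait data: {sorted(drop)}")
        tree = self._tree.clone(depth=1)
        tree.retain_taxa_with_labels(sorted(keep_set))
        return Phylogeny(tree)

    def mrca_node(self, a: str, b: str):
        for label in (a, b):
            if label not in self._tip_index:
                raise TreeError(f"tip {label!r} not in tree")
        return self._tree.mrca(taxon_labels=[a, b])

    def node_depth_profile(self, a: str, b: str) -> tuple[float, np.ndarray, bool]:
        """Depth of MRCA(a, b) and its shared depth with every tip.

        Returns ``(s_node, s_node_tip, at_root)`` where ``s_node_tip[i]`` is the
        depth of the common ancestor of the MRCA node and tip i (the node's own
        depth for descendant tips).
        """
        node = self.mrca_node(a, b)
        s_node = float(node.depth)
        n = self.n_tips
        s_nt = np.empty(n)
        inside = set(node.tip_indices)
        for i in inside:
            s_nt[i] = s_node
        anc = node.parent_node
        covered = set(inside)
        while anc is not None:
            new = set(anc.tip_indices) - covered
            for i in new:
                s_nt[i] = anc.depth
            covered |= new
            anc = anc.parent_node
        if len(covered) != n:
            raise TreeError("tree indexing is inconsistent")  # pragma: no cover
        return s_node, s_nt, node.parent_node is None


@dataclass(frozen=True)
class ModelFit:
    """ML fit of BM or OU to one trait on a tree (AIC = -2 logL + 2k)."""

    model: str  # "BM" or "OU"
    sigma2: float
    alpha: float  # 0 for BM
    root_state: float
    log_likelihood: float
    aic: float
    n_tips: int
    trait_name: str | None = None

    @property
    def n_params(self) -> int:
        return 2 if self.model == "BM" else 3


@dataclass(frozen=True)
class AncestralEstimate:
    """Reconstructed trait value at an MRCA: mean with +-1 SE variants."""

    pair: tuple[str, str]
    trait_name: str | None
    mean: float
    se: float

    @property
    def lower(self) -> float:
        return self.mean - self.se

    @property
    def upper(self) -> float:
        return self.mean + self.se

    def variant(self, which: str) -> float:
        if which not in ANCESTRAL_VARIANTS:
            raise CavepairsError(f"unknown ancestral variant {which!r}")
        return getattr(self, which) if which != "mean" else self.mean


@dataclass(frozen=True)
class DivergenceReport:
    """Extant vs ancestral Euclidean distance of a species pair, per variant."""

    pair: tuple[str, str]
    trait_set: str
    extant_distance: float
    ancestral_distances: dict
    factors: dict  # variant -> extant/ancestral, or None where ancestral == 0


# -- covariance kernels ------------------------------------------------------


def bm_covariance(tree: Phylogeny, sigma2: float) -> np.ndarray:
    """Tip covariance under Brownian motion: sigma2 times shared path length."""
    return sigma2 * tree.mrca_depths


def ou_covariance(tree: Phylogeny, alpha: float, sigma2: float) -> np.ndarray:
    """Tip covariance under root-conditioned OU (exact BM limit as alpha -> 0)."""
    if alpha <= 0:
        raise CavepairsError("ou_covariance requires alpha > 0; use bm_covariance")
    return sigma2 * _ou_unit_covariance(tree.mrca_depths, tree.tip_depths, alpha)


def _ou_unit_covariance(S: np.ndarray, t: np.ndarray, alpha: float) -> np.ndarray:
    gap = t[:, None] + t[None, :] - 2.0 * S
    return np.exp(-alpha * gap) * (-np.expm1(-2.0 * alpha * S)) / (2.0 * alpha)


# -- likelihood and fitting --------------------------------------------------


def _named_singularity(tree: Phylogeny) -> str:
    S, t = tree.mrca_depths, tree.tip_depths
    pairs = []
    for i in range(tree.n_tips):
        for j in range(i + 1, tree.n_tips):
            if abs(t[i] - S[i, j]) < 1e-14 and abs(t[j] - S[i, j]) < 1e-14:
                pairs.append((tree.tip_labels[i], tree.tip_labels[j]))
    return f"zero-distance tip pairs {pairs}" if pairs else "ill-conditioned covariance"


def _safe_cho_factor(V: np.ndarray, tree: Phylogeny):
    """Cholesky with an explicit singularity check (LAPACK can pass a zero pivot)."""
    try:
        c, low = cho_factor(V, lower=True)
    except LinAlgError as exc:
        raise SingularCovarianceError(
            f"singular tip covariance: {_named_singularity(tree)}"
        ) from exc
    diag = np.diag(c)
    # a pivot ratio near sqrt(machine eps) means a numerically singular matrix
    if not np.all(np.isfinite(c)) or np.min(diag) <= 1e-6 * np.max(diag):
        raise SingularCovarianceError(
            f"singular tip covariance: {_named_singularity(tree)}"
        )
    return c, low


def _profile_gaussian(V0: np.ndarray, y: np.ndarray, tree: Phylogeny):
    """GLS root state and ML sigma2 for covariance sigma2*V0; returns (logL, mu, sigma2)."""
    n = y.size
    c, low = _safe_cho_factor(V0, tree)
    ones = np.ones(n)
    Vi1 = cho_solve((c, low), ones)
    Viy = cho_solve((c, low), y)
    mu = float(ones @ Viy / (ones @ Vi1))
    r = y - mu
    quad = float(r @ cho_solve((c, low), r))
    if quad <= 0:
        raise CavepairsError("zero residual trait variance; likelihood degenerate")
    sigma2 = quad / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    logL = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2) + logdet + n)
    return logL, mu, sigma2


def fit_model(
    tree: Phylogeny,
    traits: Mapping[str, float],
    model: str,
    trait_name: str | None = None,
) -> ModelFit:
    """ML fit of BM or OU to one trait; every tip must carry a trait value."""
    missing = [l for l in tree.tip_labels if l not in traits]
    if missing:
        raise CavepairsError(f"tips without trait values: {missing}")
    y = np.array([float(traits[l]) for l in tree.tip_labels])
    n = y.size
    if model == "BM":
        logL, mu, sigma2 = _profile_gaussian(tree.mrca_depths, y, tree)
        k = 2
        alpha = 0.0
    elif model == "OU":

        def neg_profile(log_alpha: float) -> float:
            V0 = _ou_unit_covariance(tree.mrca_depths, tree.tip_depths, math.exp(log_alpha))
            return -_profile_gaussian(V0, y, tree)[0]

        grid_vals = np.array([neg_profile(la) for la in LOG_ALPHA_GRID])
        best = int(np.argmin(grid_vals))
        lo = LOG_ALPHA_GRID[max(best - 1, 0)]
        hi = LOG_ALPHA_GRID[min(best + 1, len(LOG_ALPHA_GRID) - 1)]
        res = minimize_scalar(
            neg_profile, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
        )
        log_alpha = float(res.x) if res.fun <= grid_vals[best] else float(LOG_ALPHA_GRID[best])
        alpha = math.exp(log_alpha)
        V0 = _ou_unit_covariance(tree.mrca_depths, tree.tip_depths, alpha)
        logL, mu, sigma2 = _profile_gaussian(V0, y, tree)
        k = 3
    else:
        raise CavepairsError(f"unknown model {model!r}; expected 'BM' or 'OU'")
    return ModelFit(
        model=model,
        sigma2=sigma2,
        alpha=alpha,
        root_state=mu,
        log_likelihood=logL,
        aic=-2.0 * logL + 2.0 * k,
        n_tips=n,
        trait_name=trait_name,
    )


def fit_ou_fixed_alpha(
    tree: Phylogeny,
    traits: Mapping[str, float],
    alpha: float,
    trait_name: str | None = None,
) -> ModelFit:
    """OU fit with alpha held fixed (root state and sigma2 still profiled).

    Useful for likelihood-surface inspection and for verifying that the OU
    likelihood converges to the BM likelihood as alpha -> 0.
    """
    if alpha <= 0:
        raise CavepairsError("alpha must be > 0")
    y = np.array([float(traits[l]) for l in tree.tip_labels])
    V0 = _ou_unit_covariance(tree.mrca_depths, tree.tip_depths, alpha)
    logL, mu, sigma2 = _profile_gaussian(V0, y, tree)
    return ModelFit(
        model="OU",
        sigma2=sigma2,
        alpha=alpha,
        root_state=mu,
        log_likelihood=logL,
        aic=-2.0 * logL + 6.0,
        n_tips=y.size,
        trait_name=trait_name,
    )


def select_model(fits: Sequence[ModelFit]) -> ModelFit:
    """Minimum-AIC fit; exact ties resolved toward the model with fewer parameters."""
    if len(fits) < 2:
        raise CavepairsError("select_model needs at least 2 candidate fits")
    return min(fits, key=lambda f: (f.aic, f.n_params))


# -- ancestral reconstruction ------------------------------------------------


def reconstruct_ancestor(
    tree: Phylogeny,
    traits: Mapping[str, float],
    fit: ModelFit,
    pair: tuple[str, str],
) -> AncestralEstimate:
    """Conditional mean/SE of the trait at MRCA(pair) given all tips under ``fit``.

    The node is treated as one more Gaussian coordinate of the fitted process at
    its depth; the estimate is the conditional expectation given the tips with
    the fitted (GLS) root state plugged in, and the SE is the square root of the
    GLS prediction variance — the conditional variance plus the contribution of
    root-state estimation error, so uncertainty does not artificially vanish at
    nodes near the root.
    """
    y = np.array([float(traits[l]) for l in tree.tip_labels])
    s_node, s_nt, at_root = tree.node_depth_profile(*pair)
    if at_root:
        warnings.warn(
            f"MRCA of {pair} is the tree root; reconstruction accuracy decays toward the root"
        )
    S, t = tree.mrca_depths, tree.tip_depths
    if fit.model == "BM":
        V = fit.sigma2 * S
        c = fit.sigma2 * s_nt
        v_node = fit.sigma2 * s_node
    else:
        a = fit.alpha
        V = fit.sigma2 * _ou_unit_covariance(S, t, a)
        gap = s_node + t - 2.0 * s_nt
        c = fit.sigma2 * np.exp(-a * gap) * (-np.expm1(-2.0 * a * s_nt)) / (2.0 * a)
        v_node = fit.sigma2 * (-np.expm1(-2.0 * a * s_node)) / (2.0 * a)
    cf = _safe_cho_factor(V, tree)
    w = cho_solve(cf, c)
    mean = fit.root_state + float(w @ (y - fit.root_state))
    ones = np.ones(tree.n_tips)
    Vi1 = cho_solve(cf, ones)
    # GLS prediction variance: conditional variance + root-estimation term
    var = v_node - float(w @ c) + (1.0 - float(w @ ones)) ** 2 / float(ones @ Vi1)
    se = math.sqrt(max(var, 0.0))
    return AncestralEstimate(pair=pair, trait_name=fit.trait_name, mean=mean, se=se)


def sister_species(tree: Phylogeny, species: str) -> str:
    """The tip sharing the deepest MRCA with ``species`` (its first-level sister).

    Ties (a multi-tip sibling clade) are broken by tip order, which is
    deterministic for a given newick string.
    """
    if species not in tree.tip_labels:
        raise TreeError(f"tip {species!r} not in tree")
    i = tree.tip_labels.index(species)
    s = tree.mrca_depths[i].copy()
    s[i] = -np.inf
    return tree.tip_labels[int(np.argmax(s))]


# -- divergence factors ------------------------------------------------------


def ancestral_pair_distance(
    estimates_a: Sequence[AncestralEstimate],
    estimates_b: Sequence[AncestralEstimate],
    variant: str,
) -> float:
    """Euclidean distance between the two ancestors' variant-``variant`` trait vectors.

    The variant vector of a species applies mean - SE / mean / mean + SE
    coordinate-wise.
    """
    if len(estimates_a) != len(estimates_b) or not estimates_a:
        raise CavepairsError("ancestral estimate vectors must be non-empty and aligned")
    va = np.array([e.variant(variant) for e in estimates_a])
    vb = np.array([e.variant(variant) for e in estimates_b])
    return float(np.linalg.norm(va - vb))


def divergence_report(
    pair: tuple[str, str],
    trait_set: str,
    extant_distance: float,
    ancestral_distances: Mapping[str, float],
) -> DivergenceReport:
    """Extant/ancestral distance ratios per ancestral variant (lower/mean/upper).

    A zero ancestral distance leaves that variant's factor undefined (``None``).
    """
    if extant_distance < 0 or any(d < 0 for d in ancestral_distances.values()):
        raise CavepairsError("distances must be non-negative")
    factors = {
        v: (extant_distance / d if d > 0 else None)
        for v, d in ancestral_distances.items()
    }
    return DivergenceReport(
        pair=pair,
        trait_set=trait_set,
        extant_distance=float(extant_distance),
        ancestral_distances=dict(ancestral_distances),
        factors=factors,
    )
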