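"""Fusion of imaging and clinicopathological risk factors.

Stages: (1) a pairwise dependence screen over the five risk factors
(Fisher's exact test on each of the 10 unordered pairs, Benjamini-Hochberg
adjusted at FDR 0.1); (2) a Cox proportional-hazards risk score over the
four TILs variables, dichotomised at the training-median linear predictor;
(3) a discrete Bayesian network over {Age, Grade, Size, GAN risk, TILs
risk, BCE} learned by hill climbing on the AIC score under role
constraints (Age can only be a parent, the breast-cancer-event node only a
child); (4) exact inference of P(BCE | evidence) by enumeration;
(5) leave-one-out validation and Kaplan-Meier stratification of the
predicted risk groups.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.special import gammaln
from scipy.stats import rankdata
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LEVEL_ORDERS", "DEFAULT_FACTORS", "DEFAULT_CONSTRAINTS",
    "fisher_exact", "bh_adjust", "screen_pairs", "PairScreenResult",
    "TilsRiskModel", "fit_tils_risk",
    "learn_structure", "StructureResult", "BayesNet", "fit_cpts",
    "predict_bce", "loocv_auc", "km_stratify", "mann_whitney_auc",
]

#: canonical level order per network node
LEVEL_ORDERS = {
    "age_group": ("le50", "gt50"),
    "size_group": ("le20", "gt20"),
    "grade": ("low", "intermediate", "high"),
    "gan_risk": ("low", "high"),
    "tils_risk": ("low", "high"),
    "bce": (0, 1),
}

DEFAULT_FACTORS = ("age_group", "size_group", "grade", "tils_risk",
                   "gan_risk")
DEFAULT_NODES = ("age_group", "grade", "size_group", "gan_risk",
                 "tils_risk", "bce")
#: role constraints: Age admits no incoming edge, BCE no outgoing edge
DEFAULT_CONSTRAINTS = {"no_parents": ("age_group",), "no_children": ("bce",)}

TILS_VARIABLES = ("lymphocyte", "touching_tils", "circumferential",
                  "hotspot")
_TILS_POSITIVE = {"lymphocyte": "gt5", "touching_tils": "gt0",
                  "circumferential": "yes", "hotspot": "dense"}


# ---------------------------------------------------------------------------
# Fisher exact test (Freeman-Halton for one 3-level margin)
# ---------------------------------------------------------------------------

def _table_logp_const(r, c, n):
    return (gammaln(np.asarray(r) + 1).sum()
            + gammaln(np.asarray(c) + 1).sum() - gammaln(n + 1))


def fisher_exact(table) -> float:
    """Two-sided exact p for an R x C count table (R, C in {2, 3}).

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of tables no more probable than the
    observed one (Freeman-Halton extension when a margin has 3 levels).
    Zero-margin rows/columns are dropped with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("need a 2-D nonnegative integer table")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns")
        t = t[keep_r][:, keep_c]
    if t.shape[0] not in (1, 2, 3) or t.shape[1] not in (1, 2, 3):
        raise ValueError(f"unsupported table shape {t.shape}")
    if 1 in t.shape:
        return 1.0
    if t.shape[0] == 3 and t.shape[1] == 2:
        t = t.T
    n = int(t.sum())
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    const = _table_logp_const(r, c, n)

    def cell_term(x, m):
        return gammaln(x + 1) + gammaln(m - x + 1)

    if t.shape == (2, 2):
        a = np.arange(max(0, r[0] - c[1]), min(r[0], c[0]) + 1)
        b = r[0] - a
        logp = const - cell_term(a, c[0]) - cell_term(b, c[1])
        logp_obs = const - cell_term(t[0, 0], c[0]) - cell_term(t[0, 1], c[1])
    elif t.shape[0] == 2:  # 2 x 3
        a = np.arange(0, min(r[0], c[0]) + 1)
        b = np.arange(0, min(r[0], c[1]) + 1)
        A, B = np.meshgrid(a, b, indexing="ij")
        D = r[0] - A - B
        valid = (D >= 0) & (D <= c[2])
        A, B, D = A[valid], B[valid], D[valid]
        logp = (const - cell_term(A, c[0]) - cell_term(B, c[1])
                - cell_term(D, c[2]))
        logp_obs = (const - cell_term(t[0, 0], c[0])
                    - cell_term(t[0, 1], c[1]) - cell_term(t[0, 2], c[2]))
    else:  # 3 x 3: scalar recursion (used only for small tables)
        logps = []

        def rec(row, remaining_cols, acc):
            if row == 2:
                x = remaining_cols
                logps.append(acc - sum(gammaln(v + 1) for v in x))
                return
            cells = []

            def fill(j, left, cols, a):
                if j == 2:
                    x = left
                    if 0 <= x <= cols[2]:
                        rec(row + 1,
                            (cols[0] - cells[0], cols[1] - cells[1],
                             cols[2] - x),
                            a - gammaln(x + 1))
                    return
                for v in range(min(left, cols[j]) + 1):
                    cells.append(v)
                    fill(j + 1, left - v, cols, a - gammaln(v + 1))
                    cells.pop()

            fill(0, r[row], remaining_cols, acc)

        rec(0, tuple(c), const)
        logp = np.array(logps)
        logp_obs = const - gammaln(t + 1).sum()

    p = float(np.exp(logp[logp <= logp_obs + 1e-7]).sum())
    return min(p, 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PairScreenResult:
    """All-pairs Fisher screen with BH adjustment."""

    table: pd.DataFrame
    fdr: float = 0.1

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.table[self.table["significant"].fillna(False).astype(bool)]
        return list(zip(sig["factor_a"], sig["factor_b"]))


def screen_pairs(records: pd.DataFrame, factors=DEFAULT_FACTORS,
                 fdr: float = 0.1) -> PairScreenResult:
    """Fisher exact test on every unordered factor pair, BH-adjusted.

    Missing values are dropped pairwise (complete cases per pair).  A pair
    where either factor shows fewer than two levels among the complete
    cases is flagged untestable (p = NaN) and excluded from the adjustment.
    """
    rows = []
    for fa, fb in itertools.combinations(factors, 2):
        sub = records[[fa, fb]].dropna()
        ct = pd.crosstab(sub[fa], sub[fb])
        if ct.shape[0] < 2 or ct.shape[1] < 2:
            rows.append({"factor_a": fa, "factor_b": fb, "p": np.nan,
                         "testable": False})
            continue
        rows.append({"factor_a": fa, "factor_b": fb,
                     "p": fisher_exact(ct.values), "testable": True})
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    testable = df["testable"].to_numpy()
    if testable.any():
        df.loc[testable, "p_adj"] = bh_adjust(df.loc[testable, "p"])
    df["significant"] = pd.Series(df["p_adj"] <= fdr,
                                  dtype="boolean").where(
        pd.Series(testable), pd.NA)
    return PairScreenResult(df, fdr=fdr)


# ---------------------------------------------------------------------------
# TILs risk score (Cox PH, Breslow ties)
# ---------------------------------------------------------------------------

def _tils_design(records: pd.DataFrame) -> np.ndarray:
    X = np.column_stack([
        (records[v].astype(str) == _TILS_POSITIVE[v]).astype(float)
        for v in TILS_VARIABLES])
    return X


@dataclass
class TilsRiskModel:
    """Cox-based TILs dichotomiser: linear predictor vs training median."""

    coefficients: np.ndarray
    median_lp: float

    def linear_predictor(self, records: pd.DataFrame) -> np.ndarray:
        return _tils_design(records) @ self.coefficients

    def __call__(self, records: pd.DataFrame) -> np.ndarray:
        """Label each record 'low' (lp <= training median) or 'high'."""
        lp = self.linear_predictor(records)
        return np.where(lp <= self.median_lp + 1e-12, "low", "high")


def fit_tils_risk(train_records: pd.DataFrame) -> TilsRiskModel:
    """Proportional-hazards fit on the four binary TILs covariates.

    Partial likelihood with Breslow tie handling; the returned model
    dichotomises any record at the training-set median linear predictor.
    Raises if the training data contain no events.
    """
    events = train_records["bce"].astype(int).to_numpy()
    if events.sum() == 0:
        raise ValueError("no events in training data; cannot fit Cox model")
    times = train_records["followup_years"].astype(float).to_numpy()
    X = _tils_design(train_records)
    keep = X.std(axis=0) > 0
    coefs = np.zeros(X.shape[1])
    if keep.any():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = PHReg(times, X[:, keep], status=events,
                            ties="breslow").fit(disp=False)
            coefs[keep] = fit.params
        except Exception:  # degenerate likelihood: fall back to null model
            pass
    lp = X @ coefs
    return TilsRiskModel(coefficients=coefs,
                         median_lp=float(np.median(lp)))


# ---------------------------------------------------------------------------
# structure learning (hill climbing, AIC, role constraints)
# ---------------------------------------------------------------------------

def _encode(records: pd.DataFrame, nodes) -> tuple[np.ndarray, list, dict]:
    """Complete-case integer coding of the node columns."""
    sub = records[list(nodes)].dropna()
    if len(sub) == 0:
        raise ValueError("no complete-case records over the network nodes")
    levels = {}
    codes = np.empty((len(sub), len(nodes)), dtype=np.int64)
    for j, node in enumerate(nodes):
        observed = sub[node].unique().tolist()
        lv = LEVEL_ORDERS.get(node)
        if lv is None:
            lv = tuple(sorted(observed, key=str))
        else:
            # the category space is fixed a priori; unseen levels stay in
            # the model (smoothing keeps their CPT rows defined)
            extra = sorted((v for v in observed if v not in lv), key=str)
            lv = tuple(lv) + tuple(extra)
        levels[node] = lv
        lut = {v: i for i, v in enumerate(lv)}
        codes[:, j] = sub[node].map(lut).to_numpy()
    return codes, list(nodes), levels


class _Scorer:
    """Cached per-family AIC contributions: loglik - free parameters."""

    def __init__(self, codes: np.ndarray, cards: list[int]):
        self.codes = codes
        self.cards = cards
        self.n = codes.shape[0]
        self._cache: dict = {}

    def family(self, node: int, parents: frozenset) -> float:
        key = (node, parents)
        if key in self._cache:
            return self._cache[key]
        ps = sorted(parents)
        card = self.cards[node]
        q = 1
        idx = np.zeros(self.n, dtype=np.int64)
        for p in ps:
            idx = idx * self.cards[p] + self.codes[:, p]
            q *= self.cards[p]
        idx = idx * card + self.codes[:, node]
        counts = np.bincount(idx, minlength=q * card).reshape(q, card)
        row_tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = counts * (np.log(counts) - np.log(row_tot))
        loglik = float(np.nansum(np.where(counts > 0, ll, 0.0)))
        n_params = q * (card - 1)
        score = loglik - n_params
        self._cache[key] = score
        return score


def _has_cycle(parents: dict, nodes) -> bool:
    color = {v: 0 for v in nodes}

    def dfs(v):
        color[v] = 1
        for p in parents[v]:
            if color[p] == 1 or (color[p] == 0 and dfs(p)):
                return True
        color[v] = 2
        return False

    return any(color[v] == 0 and dfs(v) for v in nodes)


@dataclass
class StructureResult:
    """Learned DAG with its score and per-restart AIC trajectories."""

    edges: list
    score: float
    nodes: list
    trajectories: list = field(default_factory=list)


def _climb(parents: dict, scorer: _Scorer, node_ix: dict, nodes,
           allowed) -> tuple[dict, float, list[float]]:
    def total():
        return sum(scorer.family(node_ix[v], frozenset(
            node_ix[p] for p in parents[v])) for v in nodes)

    score = total()
    trajectory = [score]
    while True:
        best_delta, best_apply = 0.0, None
        for a, b in itertools.product(nodes, nodes):
            if a == b:
                continue
            fam_b = frozenset(node_ix[p] for p in parents[b])
            if a not in parents[b] and (a, b) in allowed:
                trial = dict(parents)
                trial[b] = parents[b] | {a}
                if not _has_cycle(trial, nodes):
                    delta = (scorer.family(node_ix[b], fam_b | {node_ix[a]})
                             - scorer.family(node_ix[b], fam_b))
                    if delta > best_delta + 1e-9:
                        best_delta, best_apply = delta, trial
            if a in parents[b]:
                # removal
                trial = dict(parents)
                trial[b] = parents[b] - {a}
                delta = (scorer.family(node_ix[b],
                                       fam_b - {node_ix[a]})
                         - scorer.family(node_ix[b], fam_b))
                if delta > best_delta + 1e-9:
                    best_delta, best_apply = delta, trial
                # reversal
                if (b, a) in allowed:
                    trial = dict(parents)
                    trial[b] = parents[b] - {a}
                    trial[a] = parents[a] | {b}
                    if not _has_cycle(trial, nodes):
                        fam_a = frozenset(node_ix[p] for p in parents[a])
                        delta = (
                            scorer.family(node_ix[b], fam_b - {node_ix[a]})
                            - scorer.family(node_ix[b], fam_b)
                            + scorer.family(node_ix[a],
                                            fam_a | {node_ix[b]})
                            - scorer.family(node_ix[a], fam_a))
                        if delta > best_delta + 1e-9:
                            best_delta, best_apply = delta, trial
        if best_apply is None:
            break
        parents = best_apply
        score += best_delta
        trajectory.append(score)
    return parents, score, trajectory


def learn_structure(records: pd.DataFrame, constraints=None,
                    nodes=None, restarts: int = 10,
                    seed: int = 0) -> StructureResult:
    """Greedy hill climbing over add/remove/reverse moves under the AIC.

    Score = sum of per-node multinomial log-likelihoods minus the number of
    free CPT parameters; moves violating acyclicity or the role constraints
    are excluded; ties are broken by lexicographic move order.  Restart 0
    starts from the empty graph; further seeded restarts start from random
    constraint-respecting DAGs, and the best-scoring local optimum wins.
    """
    constraints = DEFAULT_CONSTRAINTS if constraints is None else constraints
    if nodes is None:
        nodes = [n for n in DEFAULT_NODES if n in records.columns]
    codes, nodes, levels = _encode(records, nodes)
    cards = [len(levels[v]) for v in nodes]
    scorer = _Scorer(codes, cards)
    node_ix = {v: j for j, v in enumerate(nodes)}
    no_parents = set(constraints.get("no_parents", ()))
    no_children = set(constraints.get("no_children", ()))
    allowed = {(a, b) for a in nodes for b in nodes
               if a != b and b not in no_parents and a not in no_children}

    rng = np.random.default_rng(seed)
    best = None
    trajectories = []
    for r in range(max(1, restarts)):
        parents = {v: frozenset() for v in nodes}
        if r > 0:
            order = list(rng.permutation(nodes))
            for i, b in enumerate(order):
                for a in order[:i]:
                    if (a, b) in allowed and rng.random() < 0.3:
                        parents[b] = parents[b] | {a}
        final, score, traj = _climb(parents, scorer, node_ix, nodes, allowed)
        trajectories.append(traj)
        if best is None or score > best[1] + 1e-9:
            best = (final, score)
    parents, score = best
    edges = sorted((p, v) for v in nodes for p in parents[v])
    return StructureResult(edges=edges, score=score, nodes=nodes,
                           trajectories=trajectories)


# ---------------------------------------------------------------------------
# CPTs and inference
# ---------------------------------------------------------------------------

class BayesNet:
    """Discrete Bayesian network: DAG + per-node CPTs.

    ``cpts[node]`` has shape (n_parent_configs, n_levels); parent
    configurations are indexed in mixed radix over the node's parents in
    listed order (first parent most significant).
    """

    def __init__(self, nodes, levels, parents, cpts, alpha=1.0,
                 constraints=None):
        self.nodes = list(nodes)
        self.levels = {v: tuple(levels[v]) for v in self.nodes}
        self.parents = {v: tuple(parents.get(v, ())) for v in self.nodes}
        self.cpts = cpts
        self.alpha = alpha
        self.constraints = constraints or DEFAULT_CONSTRAINTS
        self.validate()

    @property
    def edges(self):
        return sorted((p, v) for v in self.nodes for p in self.parents[v])

    def validate(self):
        for v in self.nodes:
            q = int(np.prod([len(self.levels[p])
                             for p in self.parents[v]])) if self.parents[v] \
                else 1
            cpt = self.cpts[v]
            if cpt.shape != (q, len(self.levels[v])):
                raise ValueError(f"CPT shape mismatch at node {v!r}")
            if not np.allclose(cpt.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows of {v!r} do not sum to 1")
        for v in self.constraints.get("no_parents", ()):
            if v in self.parents and self.parents[v]:
                raise ValueError(f"constraint violation: {v!r} has parents")
        for v in self.constraints.get("no_children", ()):
            for w in self.nodes:
                if v in self.parents[w]:
                    raise ValueError(
                        f"constraint violation: {v!r} has child {w!r}")

    def _row_index(self, node, assignment) -> int:
        idx = 0
        for p in self.parents[node]:
            idx = idx * len(self.levels[p]) + assignment[p]
        return idx

    def joint_logp(self, assignment: dict) -> float:
        lp = 0.0
        for v in self.nodes:
            row = self._row_index(v, assignment)
            lp += np.log(self.cpts[v][row, assignment[v]])
        return lp

    def to_json(self) -> str:
        return json.dumps({
            "nodes": self.nodes,
            "levels": {v: list(map(str, self.levels[v]))
                       for v in self.nodes},
            "parents": {v: list(self.parents[v]) for v in self.nodes},
            "cpts": {v: self.cpts[v].tolist() for v in self.nodes},
            "alpha": self.alpha,
            "constraints": {k: list(vs)
                            for k, vs in self.constraints.items()},
        }, indent=2)


def fit_cpts(records: pd.DataFrame, dag, alpha: float = 1.0,
             nodes=None, constraints=None) -> BayesNet:
    """Estimate CPTs with additive (Laplace) smoothing ``alpha``.

    ``dag`` is an iterable of (parent, child) edges.  With alpha = 0 the
    estimates are the raw MLE and unseen parent configurations fall back to
    a uniform row.
    """
    if nodes is None:
        nodes = [n for n in DEFAULT_NODES if n in records.columns]
    codes, nodes, levels = _encode(records, nodes)
    parents = {v: tuple(p for p, c in dag if c == v) for v in nodes}
    node_ix = {v: j for j, v in enumerate(nodes)}
    cpts = {}
    for v in nodes:
        card = len(levels[v])
        q = int(np.prod([len(levels[p]) for p in parents[v]])) \
            if parents[v] else 1
        idx = np.zeros(codes.shape[0], dtype=np.int64)
        for p in parents[v]:
            idx = idx * len(levels[p]) + codes[:, node_ix[p]]
        idx = idx * card + codes[:, node_ix[v]]
        counts = np.bincount(idx, minlength=q * card).reshape(
            q, card).astype(float)
        num = counts + alpha
        den = num.sum(axis=1, keepdims=True)
        empty = den.ravel() == 0  # only possible when alpha == 0
        cpt = np.where(den > 0, num / np.where(den == 0, 1, den),
                       1.0 / card)
        cpt[empty] = 1.0 / card
        cpts[v] = cpt
    return BayesNet(nodes, levels, parents, cpts, alpha=alpha,
                    constraints=constraints)


def predict_bce(bn: BayesNet, evidence: dict,
                target: str = "bce") -> float:
    """P(target = positive | evidence) by sum-product enumeration.

    Evidence maps node names to observed levels; unobserved nodes are
    summed out exactly.  The positive level is the last level of the
    target (level 1 for the 0/1 event indicator).
    """
    ev_codes = {}
    for node, value in evidence.items():
        if node not in bn.nodes:
            raise ValueError(f"unknown node {node!r}")
        if value not in bn.levels[node]:
            raise ValueError(f"unknown level {value!r} for node {node!r}")
        ev_codes[node] = bn.levels[node].index(value)
    free = [v for v in bn.nodes if v not in ev_codes and v != target]
    mass = np.zeros(len(bn.levels[target]))
    for combo in itertools.product(*[range(len(bn.levels[v]))
                                     for v in free]):
        assignment = dict(ev_codes)
        assignment.update(zip(free, combo))
        for t_code in range(len(bn.levels[target])):
            assignment[target] = t_code
            mass[t_code] += np.exp(bn.joint_logp(assignment))
    total = mass.sum()
    if total == 0:
        return 0.5
    return float(mass[-1] / total)


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the normalised Mann-Whitney U statistic (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both outcome classes for an AUC")
    r = rankdata(s)
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def loocv_auc(records: pd.DataFrame, constraints=None, alpha: float = 1.0,
              restarts: int = 3, seed: int = 0,
              relearn_structure: bool = True, dag=None,
              nodes=None) -> tuple[np.ndarray, float]:
    """Leave-one-out validation of the fused network.

    Each patient is removed in turn; by default both structure and CPTs are
    refit on the remainder (set ``relearn_structure=False`` with a fixed
    ``dag`` to refit parameters only), and the held-out patient's BCE
    probability is predicted from their non-outcome evidence.  Returns the
    per-patient probabilities (NaN where a fold was untrainable) and the
    Mann-Whitney AUC over the valid folds.
    """
    if nodes is None:
        nodes = [n for n in DEFAULT_NODES if n in records.columns]
    data = records.reset_index(drop=True)
    n = len(data)
    if n < 10:
        raise ValueError("need at least 10 records for leave-one-out")
    probs = np.full(n, np.nan)
    for i in range(n):
        train = data.drop(index=i)
        if train["bce"].nunique() < 2:
            warnings.warn(f"fold {i}: single-class training data; excluded")
            continue
        if relearn_structure:
            structure = learn_structure(train, constraints=constraints,
                                        nodes=nodes, restarts=restarts,
                                        seed=seed)
            fold_dag = structure.edges
        else:
            if dag is None:
                raise ValueError("fixed-structure mode requires a dag")
            fold_dag = dag
        bn = fit_cpts(train, fold_dag, alpha=alpha, nodes=nodes,
                      constraints=constraints)
        row = data.iloc[i]
        evidence = {v: row[v] for v in bn.nodes
                    if v != "bce" and pd.notna(row[v])}
        probs[i] = predict_bce(bn, evidence)
    valid = ~np.isnan(probs)
    auc = mann_whitney_auc(probs[valid],
                           data.loc[valid, "bce"].astype(int))
    return probs, auc


def km_stratify(records: pd.DataFrame, probabilities, cut: float,
                horizon: float = 5.0):
    """Kaplan-Meier curves and log-rank test for predicted risk groups.

    Patients with predicted probability >= ``cut`` form the high-risk
    group.  Time is follow-up administratively censored at ``horizon``
    years; the event indicator is the BCE flag (events after the horizon
    count as censored).  Returns ({"low": df, "high": df}, logrank_p,
    logrank_statistic) where each df tabulates (time, at_risk, events,
    survival).
    """
    probs = np.asarray(probabilities, dtype=float)
    times = np.minimum(records["followup_years"].astype(float).to_numpy(),
                       horizon)
    events = (records["bce"].astype(int).to_numpy()
              & (records["followup_years"].astype(float).to_numpy()
                 <= horizon + 1e-12))
    high = probs >= cut
    if high.all() or (~high).all():
        raise ValueError("risk cut produces an empty group")
    curves = {}
    for name, sel in (("low", ~high), ("high", high)):
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=name)
        ev = kmf.event_table
        curves[name] = pd.DataFrame({
            "time": ev.index.to_numpy(),
            "at_risk": ev["at_risk"].to_numpy(),
            "events": ev["observed"].to_numpy(),
            "survival": kmf.survival_function_[name].to_numpy(),
        })
    lr = logrank_test(times[~high], times[high],
                      event_observed_A=events[~high],
                      event_observed_B=events[high])
    return curves, float(lr.p_value), float(lr.test_statistic)
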