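"""Rearrangement-signature extraction and patient grouping.

The per-patient catalogue combines SV type, size and degree of
clustering into 32 channels: {clustered, non-clustered} x ({DEL, DUP,
INV} x 5 size bins + translocation). Signatures are extracted by
non-negative matrix factorization (multiplicative updates, Frobenius
objective) over random restarts; the factorization rank is chosen by
combining cophenetic and silhouette stability scores. Patients are then
grouped by consensus clustering of their exposure proportions, and
orthogonal tumour features are associated with signature presence by
univariate-then-stepwise logistic regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

SIZE_BIN_EDGES = [0.0, 1e4, 1e5, 1e6, 1e7, math.inf]
SIZE_BIN_LABELS = ["<10kb", "10-100kb", "100kb-1Mb", "1-10Mb", ">10Mb"]
CLUSTERING_LABELS = ("clustered", "non-clustered")
INTRA_TYPES = ("DEL", "DUP", "INV")

CHANNELS = [
    f"{cl}:{t}:{sz}"
    for cl in CLUSTERING_LABELS
    for t in INTRA_TYPES
    for sz in SIZE_BIN_LABELS
] + [f"{cl}:translocation" for cl in CLUSTERING_LABELS]


def size_bin_label(span_bp: int) -> str:
    """Half-open size bins [lo, hi); sub-1 kb SVs fall in the smallest."""
    idx = int(np.searchsorted(SIZE_BIN_EDGES, span_bp, side="right")) - 1
    idx = min(max(idx, 0), len(SIZE_BIN_LABELS) - 1)
    return SIZE_BIN_LABELS[idx]


@dataclass
class Catalogue:
    """channel x patient non-negative integer count matrix."""

    counts: pd.DataFrame  # index = CHANNELS, columns = patients

    def __post_init__(self) -> None:
        if list(self.counts.index) != CHANNELS:
            raise ValueError("catalogue rows must be the 32 standard channels")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("catalogue counts must be non-negative")

    @property
    def patients(self) -> list[str]:
        return list(self.counts.columns)

    def channel_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)


class PipelineOrderError(RuntimeError):
    """A stage ran before its prerequisite (e.g. catalogue before clustering)."""


def build_catalogue(cohort, clusters_by_patient) -> Catalogue:
    """Bin every classified SV into one of the 32 catalogue channels.

    An SV is "clustered" when its footprint class is complex. SVs in ME
    footprints are set aside (they describe retrotransposition, not a
    rearrangement process). Every remaining SV increments exactly one
    channel; an SV without a classified footprint is a pipeline-ordering
    violation.
    """
    class_by_call: dict[tuple[str, str], str] = {}
    for pid, clusters in clusters_by_patient.items():
        for cl in clusters:
            if cl.cls is None:
                raise PipelineOrderError(
                    f"cluster {cl.cluster_id} of patient {pid} has no class; "
                    "run classify_clusters first"
                )
            for mid in cl.member_ids:
                class_by_call[(pid, mid)] = cl.cls
    counts = pd.DataFrame(
        0, index=CHANNELS, columns=list(cohort.patients), dtype=int
    )
    for call in cohort.all_calls():
        cls = class_by_call.get((call.patient, call.call_id))
        if cls is None:
            raise PipelineOrderError(
                f"call {call.call_id} of patient {call.patient} has no footprint class"
            )
        if cls == "ME":
            continue
        clust = "clustered" if cls == "complex" else "non-clustered"
        if call.svtype == "BND":
            channel = f"{clust}:translocation"
        else:
            channel = f"{clust}:{call.svtype}:{size_bin_label(call.span_length)}"
        counts.loc[channel, call.patient] += 1
    return Catalogue(counts=counts)


# ---------------------------------------------------------------------------
# NMF by multiplicative updates


def nmf_mu(
    V: np.ndarray,
    k: int,
    iters: int,
    rng: np.random.Generator,
    track_objective: bool = False,
    eps: float = 1e-9,
):
    """Frobenius NMF by Lee-Seung multiplicative updates.

    Returns (W, H, objective) or, with ``track_objective``, additionally
    the per-iteration objective history (non-increasing by construction
    of the updates).
    """
    m, n = V.shape
    scale = math.sqrt(max(V.mean(), eps) / k)
    W = rng.random((m, k)) * scale + eps
    H = rng.random((k, n)) * scale + eps
    history = []
    for _ in range(iters):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        if track_objective:
            history.append(0.5 * float(np.linalg.norm(V - W @ H) ** 2))
    obj = 0.5 * float(np.linalg.norm(V - W @ H) ** 2)
    if track_objective:
        return W, H, obj, history
    return W, H, obj


@dataclass
class SignatureModel:
    k: int
    W: pd.DataFrame  # channel x k, columns sum to 1
    H: pd.DataFrame  # k x patient, >= 0
    scores: pd.DataFrame  # per-k cophenetic / silhouette / mean rank
    assignment: Optional[pd.DataFrame] = None  # filled by match_reference


def _cophenetic(consensus: np.ndarray) -> float:
    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    if np.allclose(condensed, condensed[0] if condensed.size else 0.0):
        return 1.0  # perfectly stable (or degenerate) consensus
    Z = average(condensed)
    with np.errstate(invalid="ignore"):
        c, _ = cophenet(Z, condensed)
    return float(c) if np.isfinite(c) else 1.0


def _silhouette(P: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score

    uniq = np.unique(labels)
    if len(uniq) < 2 or len(uniq) >= len(labels):
        return float("nan")
    try:
        return float(silhouette_score(P, labels))
    except ValueError:
        return float("nan")


def extract_signatures(
    catalogue: Catalogue,
    kmin: int = 2,
    kmax: int = 10,
    iters: int = 1000,
    replicates: int = 30,
    seed: int = 0,
) -> SignatureModel:
    """Extract signatures, choosing the rank by stability.

    For each k in [kmin, kmax] the factorization is restarted
    ``replicates`` times from seeded random initializations; restarts
    vote a patient consensus matrix (co-assignment of patients to their
    dominant signature), scored by the cophenetic correlation, and the
    best-objective restart is scored by the silhouette of its
    exposure-based patient clustering. The chosen k maximizes the mean
    of the two scores' ranks (ties to the smaller k). W is returned
    column-stochastic with H rescaled to compensate.
    """
    V = catalogue.counts.to_numpy(dtype=float)
    if not V.any():
        raise ValueError("catalogue is all zero; nothing to factorize")
    if kmax > V.shape[1]:
        raise ValueError("kmax exceeds the number of patients")
    if kmin < 1 or kmin > kmax:
        raise ValueError("need 1 <= kmin <= kmax")
    n = V.shape[1]
    # patient profiles in catalogue space: the k-independent frame in
    # which exposure-based clusterings of different ranks are comparable
    profiles = (V / np.maximum(V.sum(axis=0, keepdims=True), 1e-12)).T
    rows = []
    best_per_k = {}
    for k in range(kmin, kmax + 1):
        consensus = np.zeros((n, n))
        best = None
        for r in range(replicates):
            rng = np.random.default_rng([seed, k, r])
            W, H, obj = nmf_mu(V, k, iters, rng)
            labels = H.argmax(axis=0)
            consensus += (labels[:, None] == labels[None, :]).astype(float)
            if best is None or obj < best[2]:
                best = (W, H, obj)
        consensus /= replicates
        coph = _cophenetic(consensus)
        Wb, Hb, _ = best
        sil = _silhouette(profiles, Hb.argmax(axis=0))
        best_per_k[k] = (Wb, Hb)
        rows.append({"k": k, "cophenetic": coph, "silhouette": sil})
    scores = pd.DataFrame(rows).set_index("k")
    from scipy.stats import rankdata

    def _ranks(col: pd.Series) -> np.ndarray:
        vals = np.nan_to_num(col.to_numpy(), nan=-2.0)
        return rankdata(vals)

    mean_rank = (_ranks(scores["cophenetic"]) + _ranks(scores["silhouette"])) / 2
    scores["mean_rank"] = mean_rank
    chosen_k = int(scores.index[int(np.argmax(mean_rank))])
    W, H = best_per_k[chosen_k]
    col_sums = np.maximum(W.sum(axis=0), 1e-12)
    W = W / col_sums
    H = H * col_sums[:, None]
    sig_names = [f"S{i + 1}" for i in range(chosen_k)]
    return SignatureModel(
        k=chosen_k,
        W=pd.DataFrame(W, index=CHANNELS, columns=sig_names),
        H=pd.DataFrame(H, index=sig_names, columns=catalogue.patients),
        scores=scores,
    )


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def match_reference(W: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Assign each extracted signature a reference name by cosine similarity.

    Channel labels must agree as sets (rows are reordered by label).
    Greedy without replacement by descending cosine; extracted
    signatures left over once references are exhausted get no name.
    """
    if set(W.index) != set(reference.index):
        raise ValueError("channel labels of W and reference disagree")
    ref = reference.loc[W.index]
    sims = np.array(
        [
            [cosine_similarity(W[s].to_numpy(), ref[r].to_numpy()) for r in ref.columns]
            for s in W.columns
        ]
    )
    pairs = sorted(
        ((sims[i, j], i, j) for i in range(sims.shape[0]) for j in range(sims.shape[1])),
        reverse=True,
    )
    used_s: set[int] = set()
    used_r: set[int] = set()
    assigned: dict[int, tuple[Optional[str], float]] = {}
    for cos, i, j in pairs:
        if i in used_s or j in used_r:
            continue
        used_s.add(i)
        used_r.add(j)
        assigned[i] = (ref.columns[j], cos)
    rows = []
    for i, s in enumerate(W.columns):
        name, cos = assigned.get(i, (None, float("nan")))
        rows.append({"signature": s, "reference": name, "cosine": cos})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Consensus clustering of exposures


@dataclass
class PatientGroups:
    K: int
    labels: dict[str, int]  # patient -> 1..K
    mean_consensus: dict[int, float]  # per candidate K
    consensus: np.ndarray  # consensus matrix at chosen K


def consensus_group(
    H: pd.DataFrame,
    Kmax: int,
    resamples: int = 1000,
    subsample: float = 0.8,
    seed: int = 0,
    Kmin: int = 2,
) -> PatientGroups:
    """Group patients by consensus k-means on exposure proportions.

    For each K in [Kmin, Kmax], patients are repeatedly subsampled and
    k-means-clustered on per-patient exposure proportions; the pairwise
    consensus matrix (co-assignment frequency among co-sampled pairs)
    is cut by average-linkage hierarchical clustering into K groups.
    The chosen K maximizes the mean within-group consensus (singleton
    groups count as 1), ties to the smaller K.
    """
    from sklearn.cluster import KMeans

    patients = list(H.columns)
    n = len(patients)
    if Kmax > n:
        raise ValueError("Kmax exceeds the number of patients")
    P = (H / np.maximum(H.sum(axis=0), 1e-12)).to_numpy().T  # patients x k
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample * n)))
    results = {}
    for K in range(Kmin, Kmax + 1):
        co_assigned = np.zeros((n, n))
        co_sampled = np.zeros((n, n))
        for _ in range(resamples):
            idx = rng.choice(n, size=m, replace=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # duplicate points are fine
                km = KMeans(
                    n_clusters=K,
                    n_init=3,
                    random_state=int(rng.integers(2**31)),
                ).fit(P[idx])
            lab = km.labels_
            same = (lab[:, None] == lab[None, :]).astype(float)
            co_assigned[np.ix_(idx, idx)] += same
            co_sampled[np.ix_(idx, idx)] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(co_sampled > 0, co_assigned / co_sampled, 0.0)
        np.fill_diagonal(consensus, 1.0)
        D = 1.0 - consensus
        np.fill_diagonal(D, 0.0)
        condensed = squareform(D, checks=False)
        Z = average(condensed)
        labels = fcluster(Z, t=K, criterion="maxclust")
        group_scores = []
        for g in np.unique(labels):
            members = np.flatnonzero(labels == g)
            if len(members) < 2:
                group_scores.append(1.0)
            else:
                sub = consensus[np.ix_(members, members)]
                iu = np.triu_indices(len(members), 1)
                group_scores.append(float(sub[iu].mean()))
        results[K] = (float(np.mean(group_scores)), labels, consensus)
    mean_scores = {K: v[0] for K, v in results.items()}
    chosen_K = max(sorted(results), key=lambda K: mean_scores[K])
    _, labels, consensus = results[chosen_K]
    # relabel contiguously by first appearance
    remap: dict[int, int] = {}
    final: dict[str, int] = {}
    for pid, lab in zip(patients, labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        final[pid] = remap[lab]
    return PatientGroups(
        K=len(remap), labels=final, mean_consensus=mean_scores, consensus=consensus
    )


# ---------------------------------------------------------------------------
# Feature association (logistic regression) and group comparisons


def _transform_features(features: pd.DataFrame) -> pd.DataFrame:
    X = np.log1p(features.astype(float))
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = sd.replace(0.0, 1.0)
    return (X - mu) / sd


def _is_separated(x: np.ndarray, y: np.ndarray) -> bool:
    x0, x1 = x[y == 0], x[y == 1]
    if len(x0) == 0 or len(x1) == 0:
        return True
    return x0.max() < x1.min() or x1.max() < x0.min()


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    import statsmodels.api as sm

    exog = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, exog)
        res = model.fit(disp=0, maxiter=200)
    return res


def associate_features(
    rs_presence: pd.DataFrame,
    feature_table: pd.DataFrame,
    p_enter: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariate then stepwise-multivariate logistic association.

    Features are log(x+1)-transformed and standardized. Per response
    (signature presence, binary), each feature is fit univariately;
    survivors at p < ``p_enter`` seed a multivariate logistic model
    refined by bidirectional stepwise AIC, with Benjamini-Hochberg
    q-values on the final model's coefficients. Complete separation is
    reported as a flag instead of a spurious estimate.
    """
    from statsmodels.stats.multitest import multipletests

    X = _transform_features(feature_table)
    X = X.loc[rs_presence.index]
    uni_rows = []
    multi_rows = []
    for rs in rs_presence.columns:
        y = rs_presence[rs].astype(int).to_numpy()
        survivors = []
        for feat in X.columns:
            x = X[feat].to_numpy()
            if y.min() == y.max():
                uni_rows.append(
                    dict(response=rs, feature=feat, log_odds=np.nan, p=np.nan,
                         flag="constant_response")
                )
                continue
            if _is_separated(x, y):
                uni_rows.append(
                    dict(response=rs, feature=feat, log_odds=np.nan, p=np.nan,
                         flag="separation")
                )
                continue
            try:
                res = _fit_logit(y, X[[feat]])
                lo, p = float(res.params[feat]), float(res.pvalues[feat])
                flag = "" if res.mle_retvals.get("converged", True) else "no_convergence"
            except Exception:
                lo, p, flag = np.nan, np.nan, "fit_failed"
            uni_rows.append(
                dict(response=rs, feature=feat, log_odds=lo, p=p, flag=flag)
            )
            if flag == "" and p < p_enter:
                survivors.append(feat)
        if not survivors or y.min() == y.max():
            continue
        selected = _stepwise_aic(y, X, survivors)
        if not selected:
            continue
        try:
            res = _fit_logit(y, X[selected])
        except Exception:
            for feat in selected:
                multi_rows.append(
                    dict(response=rs, feature=feat, log_odds=np.nan, p=np.nan,
                         q=np.nan, flag="fit_failed")
                )
            continue
        ps = [float(res.pvalues[f]) for f in selected]
        qs = multipletests(ps, method="fdr_bh")[1]
        for feat, p, q in zip(selected, ps, qs):
            multi_rows.append(
                dict(
                    response=rs,
                    feature=feat,
                    log_odds=float(res.params[feat]),
                    p=p,
                    q=float(q),
                    flag="" if res.mle_retvals.get("converged", True) else "no_convergence",
                )
            )
    uni = pd.DataFrame(uni_rows, columns=["response", "feature", "log_odds", "p", "flag"])
    multi = pd.DataFrame(
        multi_rows, columns=["response", "feature", "log_odds", "p", "q", "flag"]
    )
    return uni, multi


def _aic_of(y: np.ndarray, X: pd.DataFrame, feats: list[str]) -> float:
    try:
        res = _fit_logit(y, X[feats]) if feats else _fit_logit(y, X[[]])
        return float(res.aic)
    except Exception:
        return math.inf


def _stepwise_aic(
    y: np.ndarray, X: pd.DataFrame, candidates: list[str]
) -> list[str]:
    """Bidirectional stepwise AIC starting from the full candidate model."""
    current = list(candidates)
    current_aic = _aic_of(y, X, current)
    while True:
        moves: list[tuple[float, str, str]] = []
        for f in current:
            trial = [g for g in current if g != f]
            moves.append((_aic_of(y, X, trial), "drop", f))
        for f in candidates:
            if f not in current:
                moves.append((_aic_of(y, X, current + [f]), "add", f))
        if not moves:
            break
        best_aic, op, feat = min(moves, key=lambda t: t[0])
        if best_aic < current_aic - 1e-9:
            if op == "drop":
                current = [g for g in current if g != feat]
            else:
                current = current + [feat]
            current_aic = best_aic
        else:
            break
    return current


def holdout_validate(
    rs_presence: pd.DataFrame,
    feature_table: pd.DataFrame,
    splits: Sequence[float] = (0.8, 0.6, 0.4),
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Coefficient sign stability of the final models under hold-out refits.

    For each split fraction and replicate, the final multivariate model
    (selected once on the full data) is refit on the training fraction;
    the reported rate is the fraction of refits whose coefficient sign
    matches the full-data fit.
    """
    cols = ["response", "feature", "split", "sign_consistency"]
    if reps <= 0:
        return pd.DataFrame(columns=cols)
    _, multi = associate_features(rs_presence, feature_table)
    if multi.empty:
        return pd.DataFrame(columns=cols)
    X = _transform_features(feature_table).loc[rs_presence.index]
    rng = np.random.default_rng(seed)
    rows = []
    for rs, sub in multi.groupby("response", sort=False):
        feats = list(sub["feature"])
        full_sign = {f: np.sign(lo) for f, lo in zip(sub["feature"], sub["log_odds"])}
        y = rs_presence[rs].astype(int).to_numpy()
        n = len(y)
        for frac in splits:
            hits = {f: 0 for f in feats}
            valid = 0
            for _ in range(reps):
                for _attempt in range(20):
                    idx = rng.choice(n, size=max(2, int(round(frac * n))), replace=False)
                    if 0 < y[idx].sum() < len(idx):
                        break
                else:
                    continue
                try:
                    res = _fit_logit(y[idx], X.iloc[idx][feats])
                except Exception:
                    continue
                valid += 1
                for f in feats:
                    if np.sign(float(res.params[f])) == full_sign[f]:
                        hits[f] += 1
            for f in feats:
                rows.append(
                    dict(
                        response=rs,
                        feature=f,
                        split=frac,
                        sign_consistency=hits[f] / valid if valid else np.nan,
                    )
                )
    return pd.DataFrame(rows, columns=cols)


def compare_groups(
    values: Sequence[float],
    group_labels: Sequence,
    groups: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum p-value per group pair.

    Exact test when the combined pair has <= 50 observations and no
    ties; normal approximation (with tie correction and continuity)
    otherwise.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if groups is None:
        groups = list(pd.unique(labels))
    by_group = {g: values[labels == g] for g in groups}
    for g, v in by_group.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")
    rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            x, y = by_group[g1], by_group[g2]
            combined = np.concatenate([x, y])
            no_ties = len(np.unique(combined)) == len(combined)
            method = "exact" if (len(combined) <= 50 and no_ties) else "asymptotic"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(
                    mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
                )
            rows.append(dict(group1=g1, group2=g2, p=min(p, 1.0), method=method))
    return pd.DataFrame(rows, columns=["group1", "group2", "p", "method"])
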