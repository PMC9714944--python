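"""Integer copy-number calling from the 7-assay measured-GCN vector.

The caller is a two-stage Gaussian linear discriminant analysis (LDA),
written from scratch because the estimation procedure itself is the
point of the package:

* stage 1 classifies the 4-vector of redundant total estimates
  (C4A+C4B, CYP21A1P+CYP21A2, HERV_del+HERV_ins, breakpoint+2) into an
  integer segment total T;
* stage 2 resolves each paralogous pair with an LDA on the
  (pair A, pair B, breakpoint) 3-vector, restricted to integer classes
  summing to T; a pair whose one side is unambiguously zero is assigned
  (T, 0) directly, bypassing the discriminant.

Every emitted call satisfies the four-way genomic constraint by
construction.  Reference classes come from the cohort itself (known
integer labels where available, otherwise constrained rounding), with
leave-one-out cross-validation and posterior probabilities flagging
ambiguous estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assays import ASSAYS, PARALOG_PAIRS, locus_counts_to_totals
from .core import classify_ambiguity


@dataclass(frozen=True)
class LdaModel:
    """Gaussian classifier with class means and one pooled covariance."""

    classes: tuple
    means: np.ndarray  # (K, d)
    pooled_cov: np.ndarray  # (d, d), regularized
    priors: np.ndarray  # (K,)
    regularization: float
    singleton_classes: frozenset = frozenset()

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def train_lda(features: np.ndarray, labels: list, priors: dict | None = None,
              regularization: float = 1e-6) -> LdaModel:
    """Fit class means and a pooled within-class covariance.

    The covariance uses the (N - K) denominator and is ridge-stabilized
    by ``regularization * trace / d`` on the diagonal.  Priors default
    to empirical class frequencies.  Classes of size 1 contribute their
    mean but no covariance information and are recorded as
    non-cross-validatable.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    labels = list(labels)
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("LDA needs at least two classes")
    n, d = X.shape
    k = len(classes)
    means = np.empty((k, d))
    scatter = np.zeros((d, d))
    counts = np.empty(k)
    singletons = set()
    for i, c in enumerate(classes):
        mask = np.array([lab == c for lab in labels])
        xc = X[mask]
        counts[i] = len(xc)
        if len(xc) == 1:
            singletons.add(c)
        means[i] = xc.mean(axis=0)
        centered = xc - means[i]
        scatter += centered.T @ centered
    denom = max(n - k, 1)
    cov = scatter / denom
    tr = np.trace(cov)
    ridge = regularization * (tr / d if tr > 0 else 1.0)
    cov = cov + ridge * np.eye(d)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("pooled covariance is singular even after "
                         "regularization; increase the regularization "
                         "parameter") from exc
    if priors is None:
        pr = counts / counts.sum()
    else:
        pr = np.array([priors[c] for c in classes], dtype=float)
        pr = pr / pr.sum()
    return LdaModel(classes=classes, means=means, pooled_cov=cov, priors=pr,
                    regularization=regularization,
                    singleton_classes=frozenset(singletons))


def classify(model: LdaModel, x: np.ndarray) -> tuple[object, dict]:
    """Most probable class and the softmax posterior over all classes.

    The linear discriminant of class k is
    ``x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + log pi_k``; posteriors are
    the softmax of the discriminants (exact for Gaussian classes with a
    shared covariance).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {x.shape[0]}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature vector must be finite")
    inv = np.linalg.inv(model.pooled_cov)
    deltas = np.empty(len(model.classes))
    for i, mu in enumerate(model.means):
        deltas[i] = (x @ inv @ mu - 0.5 * mu @ inv @ mu
                     + np.log(model.priors[i]))
    deltas -= deltas.max()
    post = np.exp(deltas)
    post /= post.sum()
    label = model.classes[int(np.argmax(post))]
    return label, dict(zip(model.classes, post.tolist()))


def loo_cross_validate(features: np.ndarray, labels: list,
                       priors: dict | None = None,
                       regularization: float = 1e-6) -> list[str]:
    """Leave-one-out validation: 'pass', 'fail' or 'not_applicable'.

    A sample whose class has only one member cannot be held out (its
    class would vanish from the training set) and is not applicable.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = list(labels)
    counts: dict = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    results = []
    for i, lab in enumerate(labels):
        if counts[lab] < 2:
            results.append("not_applicable")
            continue
        mask = np.ones(len(labels), dtype=bool)
        mask[i] = False
        sub = [labels[j] for j in range(len(labels)) if mask[j]]
        model = train_lda(X[mask], sub, priors=priors,
                          regularization=regularization)
        pred, _ = classify(model, X[i])
        results.append("pass" if pred == lab else "fail")
    return results


@dataclass(frozen=True)
class IntegerGcnCall:
    """Integer copy numbers for one sample, with quality flags.

    ``posterior`` is the smallest stage posterior supporting the call;
    ``cv_pass`` is False only on a leave-one-out disagreement;
    ``ambiguous`` flags a low posterior or a cross-validation failure.
    """

    sample_id: str
    total: int
    gcns: dict[str, int]
    posterior: float
    cv_pass: bool
    ambiguous: bool
    consistency_pass: bool
    stage_posteriors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        totals = locus_counts_to_totals(self.gcns)
        if any(t != self.total for t in totals):
            raise ValueError("call violates the four-way genomic constraint")


@dataclass(frozen=True)
class ReferenceSet:
    """Labeled cohort used to train the discriminants.

    ``measured`` is a (n_samples, 7) array in :data:`qgcn.assays.ASSAYS`
    order; ``labels`` the matching integer copy numbers.
    """

    sample_ids: list[str]
    measured: np.ndarray  # (n, 7)
    labels: np.ndarray  # (n, 7) integers

    def __post_init__(self) -> None:
        if self.measured.shape != self.labels.shape:
            raise ValueError("measured and labels must align")
        if self.measured.shape[1] != len(ASSAYS):
            raise ValueError(f"expected {len(ASSAYS)} assay columns")


def constrained_round(measured: dict[str, float]) -> dict[str, int]:
    """Round a measured 7-vector onto the genomic constraint surface.

    The total is the rounded mean of the four total estimates; each pair
    splits it by rounding the first member (clipped to [0, T]) and
    assigning the remainder to the counterpart.
    """
    totals = locus_counts_to_totals(measured)
    total = max(2, round(float(np.mean(totals))))
    out: dict[str, int] = {}
    for a, b in PARALOG_PAIRS:
        na = min(max(0, round(measured[a])), total)
        out[a] = na
        out[b] = total - na
    out["BP"] = total - 2
    return out


def _totals_features(measured: np.ndarray) -> np.ndarray:
    """(n, 4) array of the four total estimates from a (n, 7) GCN matrix."""
    idx = {a: i for i, a in enumerate(ASSAYS)}
    cols = []
    for a, b in PARALOG_PAIRS:
        cols.append(measured[:, idx[a]] + measured[:, idx[b]])
    cols.append(measured[:, idx["BP"]] + 2.0)
    return np.column_stack(cols)


def build_reference_set(measured_df: "pd.DataFrame",
                        known: "pd.DataFrame | None" = None) -> ReferenceSet:
    """Reference set from a sample x assay measured matrix.

    ``known`` optionally supplies integer labels (same layout); samples
    without known labels are labeled by constrained rounding of their
    own measured vector (self-training, as when a study cohort is its
    own reference).
    """
    sids = list(measured_df.index)
    X = measured_df[list(ASSAYS)].to_numpy(dtype=float)
    labels = np.empty_like(X, dtype=int)
    for i, sid in enumerate(sids):
        if known is not None and sid in known.index:
            labels[i] = [int(known.loc[sid, a]) for a in ASSAYS]
        else:
            m = dict(zip(ASSAYS, X[i]))
            r = constrained_round(m)
            labels[i] = [r[a] for a in ASSAYS]
    return ReferenceSet(sample_ids=sids, measured=X, labels=labels)


def _pair_features(measured: np.ndarray, a: str, b: str,
                   use_breakpoint: bool = True) -> np.ndarray:
    idx = {name: i for i, name in enumerate(ASSAYS)}
    cols = [idx[a], idx[b]] + ([idx["BP"]] if use_breakpoint else [])
    return measured[:, cols]


def call_sample(measured: dict[str, float], reference: ReferenceSet,
                posterior_threshold: float = 0.95,
                regularization: float = 1e-6,
                halfwidth: float = 0.3,
                run_cv: bool = True,
                use_breakpoint_feature: bool = True) -> IntegerGcnCall:
    """Two-stage LDA call of one sample against a labeled reference set.

    Missing assays are a hard error.  ``run_cv`` controls whether the
    sample's leave-one-out check is evaluated (requires the sample to be
    part of the reference set).
    """
    missing = [a for a in ASSAYS if a not in measured or measured[a] is None]
    if missing:
        raise ValueError(f"measured vector is missing assays {missing}")
    x7 = np.array([measured[a] for a in ASSAYS], dtype=float)

    # stage 1: total segment count
    feats = _totals_features(reference.measured)
    total_labels = [int(row[0] + row[1]) for row in
                    zip(reference.labels[:, 0], reference.labels[:, 1])]
    model_t = train_lda(feats, total_labels, regularization=regularization)
    x_tot = _totals_features(x7[None, :])[0]
    total, post_t = classify(model_t, x_tot)
    posteriors = {"total": post_t[total]}

    # stage 2: split each paralogous pair under the fixed total
    idx = {name: i for i, name in enumerate(ASSAYS)}
    gcns: dict[str, int] = {"BP": total - 2}
    ambiguous = False
    for a, b in PARALOG_PAIRS:
        ma, mb = measured[a], measured[b]
        lab_a, za = classify_ambiguity(ma, halfwidth)
        lab_b, zb = classify_ambiguity(mb, halfwidth)
        if lab_a == "unambiguous" and za == 0:
            gcns[a], gcns[b] = 0, total
            posteriors[a] = 1.0
            continue
        if lab_b == "unambiguous" and zb == 0:
            gcns[a], gcns[b] = total, 0
            posteriors[a] = 1.0
            continue
        pair_labels = [(int(la), int(lb)) for la, lb in
                       zip(reference.labels[:, idx[a]],
                           reference.labels[:, idx[b]])]
        keep = [i for i, (la, lb) in enumerate(pair_labels)
                if la + lb == total]
        classes_in_keep = {pair_labels[i] for i in keep}
        if len(classes_in_keep) >= 2:
            pf = _pair_features(reference.measured, a, b,
                                use_breakpoint_feature)
            model_p = train_lda(pf[keep], [pair_labels[i] for i in keep],
                                regularization=regularization)
            x_pair = ([ma, mb, measured["BP"]] if use_breakpoint_feature
                      else [ma, mb])
            (na, nb), post_p = classify(model_p, np.array(x_pair))
            posteriors[a] = post_p[(na, nb)]
        elif len(classes_in_keep) == 1:
            # only one admissible split among the references
            (na, nb), = classes_in_keep
            posteriors[a] = 1.0
        else:
            # no reference sample at this total: constrained rounding
            na = min(max(0, round(ma)), total)
            nb = total - na
            posteriors[a] = posteriors["total"]
            ambiguous = True
        gcns[a], gcns[b] = na, nb

    posterior = min(posteriors.values())
    if posterior < posterior_threshold:
        ambiguous = True

    cv_pass = True
    if run_cv:
        try:
            i_self = reference.sample_ids.index(measured.get("sample_id", ""))
        except ValueError:
            i_self = _match_row(reference, x7)
        if i_self is not None:
            cv = loo_cross_validate(feats, total_labels,
                                    regularization=regularization)
            if cv[i_self] == "fail":
                cv_pass = False
                ambiguous = True

    totals_all = locus_counts_to_totals(gcns)
    consistency = all(t == total for t in totals_all)
    return IntegerGcnCall(sample_id=str(measured.get("sample_id", "")),
                          total=int(total), gcns=gcns,
                          posterior=float(posterior), cv_pass=cv_pass,
                          ambiguous=bool(ambiguous),
                          consistency_pass=bool(consistency),
                          stage_posteriors=posteriors)


def _match_row(reference: ReferenceSet, x7: np.ndarray) -> int | None:
    d = np.abs(reference.measured - x7[None, :]).sum(axis=1)
    i = int(np.argmin(d))
    return i if d[i] < 1e-12 else None


def call_cohort(measured_df: "pd.DataFrame",
                known: "pd.DataFrame | None" = None,
                posterior_threshold: float = 0.95,
                regularization: float = 1e-6,
                halfwidth: float = 0.3) -> list[IntegerGcnCall]:
    """Call every sample of a cohort, the cohort being its own reference.

    Stage-1 leave-one-out cross-validation is computed once for the
    whole cohort and folded into the per-sample flags.
    """
    ref = build_reference_set(measured_df, known)
    feats = _totals_features(ref.measured)
    total_labels = [int(r[0] + r[1]) for r in
                    zip(ref.labels[:, 0], ref.labels[:, 1])]
    cv = loo_cross_validate(feats, total_labels, regularization=regularization)
    calls = []
    for i, sid in enumerate(ref.sample_ids):
        m = dict(zip(ASSAYS, ref.measured[i]))
        m["sample_id"] = sid
        call = call_sample(m, ref, posterior_threshold=posterior_threshold,
                           regularization=regularization,
                           halfwidth=halfwidth, run_cv=False)
        cv_pass = cv[i] != "fail"
        calls.append(IntegerGcnCall(
            sample_id=sid, total=call.total, gcns=call.gcns,
            posterior=call.posterior, cv_pass=cv_pass,
            ambiguous=call.ambiguous or not cv_pass,
            consistency_pass=call.consistency_pass,
            stage_posteriors=call.stage_posteriors))
    return calls
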