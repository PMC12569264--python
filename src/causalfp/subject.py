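"""Subject fingerprinting from dynamic modes of the causal signature.

The slow transition ``A`` and the fast interaction ``Q`` are
eigendecomposed, ``A = T^-1 Lambda T``; the (canonicalized) eigenvector
sets are the subject's *dynamic modes* — invariant directions along which
the linear dynamics evolve independently. A query recording is matched
against a labeled reference library by minimizing a permutation-aligned
sum of cosine distances between mode sets, solved exactly as a linear
assignment problem. All modes are treated as equally informative: the
eigenvalues are computed and kept but never enter the distance.

Feature modes:

- ``"slow"``  — modes of ``A`` only (default; the most subject-stable
  information lives in the slow dynamics).
- ``"full"``  — modes of ``A`` and ``Q`` concatenated.
- ``"single"`` — modes of the ``A`` matrix of a one-timescale refit
  (``identify_signature(..., single_timescale=True)``); structurally the
  same extraction as "slow" applied to that reduced model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import linear_sum_assignment

from .dynamics import CausalSignature

__all__ = [
    "ModalFeatureSet",
    "ReferenceLibrary",
    "modal_decompose",
    "aligned_set_distance",
    "identify_subject",
    "evaluate_subject_accuracy",
]

FEATURE_MODES = ("slow", "full", "single")
_EIGVEC_COND_LIMIT = 1e10


def _canonicalize_columns(V: np.ndarray) -> np.ndarray:
    """Unit-normalize columns and fix sign: dominant entry positive.

    Eigenvectors are defined only up to scale and sign; the cosine distance
    is not sign-invariant, so without this step identical systems could be
    maximally distant. Ties on the dominant magnitude break to the lowest
    row index.
    """
    V = np.array(V, dtype=float)
    norms = np.linalg.norm(V, axis=0)
    norms[norms == 0] = 1.0
    V = V / norms
    # argmax returns the first (lowest-index) maximizer, the stated tie-break
    dom = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[dom, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def _real_mode_vectors(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose ``M`` into real canonical mode vectors.

    Complex conjugate eigenpairs are replaced by the (Re, Im) pair of one
    member, keeping the feature set real while spanning the same invariant
    plane. Near-defective matrices (eigenvector condition number above
    1e10) fall back to orthogonal real Schur vectors with a warning.

    Returns (mode matrix with canonicalized columns, eigenvalues).
    """
    eigvals, eigvecs = np.linalg.eig(M)
    cond = np.linalg.cond(eigvecs)
    if not np.isfinite(cond) or cond >= _EIGVEC_COND_LIMIT:
        warnings.warn(
            f"eigenvector matrix nearly defective (cond {cond:.2e}); "
            "falling back to orthogonal Schur vectors",
            stacklevel=2,
        )
        _, Z = scipy.linalg.schur(M, output="real")
        return _canonicalize_columns(Z), eigvals

    m = M.shape[0]
    cols = np.empty((m, m))
    used = np.zeros(m, dtype=bool)
    out = 0
    for j in range(m):
        if used[j]:
            continue
        lam, v = eigvals[j], eigvecs[:, j]
        if abs(lam.imag) <= 1e-12 * max(1.0, abs(lam.real)):
            cols[:, out] = v.real
            used[j] = True
            out += 1
        else:
            # pair with its conjugate partner; keep (Re v, Im v)
            partner = None
            for k in range(j + 1, m):
                if not used[k] and np.isclose(eigvals[k], np.conj(lam)):
                    partner = k
                    break
            cols[:, out] = v.real
            cols[:, out + 1] = v.imag
            used[j] = True
            if partner is not None:
                used[partner] = True
            out += 2
    return _canonicalize_columns(cols[:, :out]), eigvals


@dataclass
class ModalFeatureSet:
    """Canonicalized dynamic-mode vectors of one signature.

    ``T_slow`` holds the slow modes (from ``A``), ``T_fast`` the fast modes
    (from ``Q``; empty unless ``feature_mode="full"``). Columns are
    unit-norm with positive dominant entry. ``eig_slow``/``eig_fast`` are
    retained for inspection but never used in matching.
    """

    T_slow: np.ndarray
    eig_slow: np.ndarray
    feature_mode: str = "slow"
    T_fast: np.ndarray | None = None
    eig_fast: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")

    @property
    def m(self) -> int:
        return self.T_slow.shape[0]

    @property
    def vectors(self) -> np.ndarray:
        """All feature vectors as columns (slow then fast)."""
        if self.feature_mode == "full" and self.T_fast is not None:
            return np.hstack([self.T_slow, self.T_fast])
        return self.T_slow


@dataclass
class ReferenceLibrary:
    """Labeled one-shot reference set for a single task condition."""

    entries: dict[str, ModalFeatureSet] = field(default_factory=dict)
    task_label: str = ""

    def add(self, subject: str, features: ModalFeatureSet) -> None:
        if subject in self.entries:
            raise ValueError(f"duplicate subject label {subject!r}")
        if self.entries:
            ref = next(iter(self.entries.values()))
            if features.m != ref.m or features.feature_mode != ref.feature_mode:
                raise ValueError("library entries must share m and feature_mode")
        self.entries[subject] = features

    def __len__(self) -> int:
        return len(self.entries)


def modal_decompose(sig: CausalSignature, feature_mode: str = "slow") -> ModalFeatureSet:
    """Extract dynamic-mode features from a signature.

    ``"slow"`` uses the modes of ``A``; ``"full"`` additionally those of
    ``Q``; ``"single"`` expects a signature from a one-timescale refit
    (``Q = 0`` forced during identification) and reads the modes of its
    ``A``.
    """
    if feature_mode not in FEATURE_MODES:
        raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")
    T_slow, eig_slow = _real_mode_vectors(sig.A)
    if feature_mode == "full":
        T_fast, eig_fast = _real_mode_vectors(sig.Q)
        return ModalFeatureSet(
            T_slow=T_slow,
            eig_slow=eig_slow,
            feature_mode="full",
            T_fast=T_fast,
            eig_fast=eig_fast,
        )
    return ModalFeatureSet(T_slow=T_slow, eig_slow=eig_slow, feature_mode=feature_mode)


def _cosine_cost(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise (1 - cosine) between columns of X and Y."""
    Xn = X / np.maximum(np.linalg.norm(X, axis=0), 1e-300)
    Yn = Y / np.maximum(np.linalg.norm(Y, axis=0), 1e-300)
    return 1.0 - Xn.T @ Yn


def aligned_set_distance(a: ModalFeatureSet, b: ModalFeatureSet) -> float:
    """Permutation-aligned cosine distance between two mode sets.

    ``min over permutations pi of sum_i (1 - cos(x_i, y_pi(i)))`` on the
    canonicalized vectors, solved exactly as a linear assignment problem.
    Symmetric and non-negative; zero iff the column sets coincide up to
    permutation (and the sign/scale absorbed by canonicalization).
    """
    X, Y = a.vectors, b.vectors
    if a.feature_mode != b.feature_mode or X.shape != Y.shape:
        raise ValueError(
            f"incompatible feature sets: {a.feature_mode}/{X.shape} vs "
            f"{b.feature_mode}/{Y.shape}"
        )
    C = _cosine_cost(X, Y)
    rows, cols = linear_sum_assignment(C)
    return float(C[rows, cols].sum())


def aligned_set_distance_bruteforce(a: ModalFeatureSet, b: ModalFeatureSet) -> float:
    """Exhaustive-enumeration reference for the aligned distance.

    Only feasible for small mode counts; kept as an independent check of
    the assignment solver.
    """
    X, Y = a.vectors, b.vectors
    C = _cosine_cost(X, Y)
    k = C.shape[0]
    best = np.inf
    for perm in itertools.permutations(range(k)):
        best = min(best, C[np.arange(k), perm].sum())
    return float(best)


def identify_subject(
    query: ModalFeatureSet, lib: ReferenceLibrary
) -> tuple[str, float, list[tuple[str, float]]]:
    """One-shot subject identification against a reference library.

    Returns the argmin-distance label, its distance, and the full ranking
    (ascending distance; ties broken by lexicographically smaller label).
    """
    if not lib.entries:
        raise ValueError("reference library is empty")
    ranked = sorted(
        ((label, aligned_set_distance(query, feats)) for label, feats in lib.entries.items()),
        key=lambda item: (item[1], item[0]),
    )
    best_label, best_dist = ranked[0]
    return best_label, best_dist, ranked


def evaluate_subject_accuracy(
    cohort: dict[tuple[str, str], CausalSignature],
    feature_mode: str = "slow",
) -> dict[str, float]:
    """Cross-condition subject-identification accuracy.

    ``cohort`` maps ``(subject, condition)`` to a signature, where
    "condition" names a run/scan (e.g. ``"run0"``, ``"run1"``). Each
    condition is taken in turn as the reference database while all other
    conditions serve as queries, so reference and query sets are always
    disjoint. Returns per-fold top-1 accuracies keyed by the reference
    condition, plus ``"mean"``.
    """
    conditions = sorted({cond for (_, cond) in cohort})
    subjects = sorted({subj for (subj, _) in cohort})
    if len(conditions) < 2:
        raise ValueError("need at least two conditions/runs per subject")

    features = {
        key: modal_decompose(sig, feature_mode) for key, sig in cohort.items()
    }
    results: dict[str, float] = {}
    for ref_cond in conditions:
        lib = ReferenceLibrary(task_label=ref_cond)
        for subj in subjects:
            if (subj, ref_cond) not in features:
                raise ValueError(
                    f"subject {subj!r} missing from reference condition {ref_cond!r}"
                )
            lib.add(subj, features[(subj, ref_cond)])
        hits = total = 0
        for (subj, cond), feats in features.items():
            if cond == ref_cond:
                continue
            pred, _, _ = identify_subject(feats, lib)
            hits += int(pred == subj)
            total += 1
        results[ref_cond] = hits / total if total else float("nan")
    results["mean"] = float(np.mean([results[c] for c in conditions]))
    return results
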