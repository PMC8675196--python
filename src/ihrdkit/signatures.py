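"""Mutational-signature refitting against a reference catalogue.

A tumor's somatic SNVs are binned into the 96 pyrimidine-strand trinucleotide
contexts (:mod:`ihrdkit.contexts`) and the L1-normalised catalog is expressed
as a non-negative mixture of reference signature profiles by constrained least
squares: minimise ``||c - S w||^2`` subject to ``w >= 0`` and ``sum(w) <= 1``.
Weights below a cutoff (default 0.06) are zeroed and the survivors are
rescaled to the pre-cutoff total, mirroring the behaviour of standard
signature-refitting tools.

The HRR-deficiency signature call used throughout the package: a tumor is
CSig3-positive when the fitted CSig3 weight exceeds 0.20, at least 50
mutations are attributed to CSig3 (weight x n_snvs), and the catalog itself is
reliable (more than 50 somatic SNVs).  CSig8 positivity uses the same weight
threshold without the attributed-count floor — an assumption, since no
published rule exists for that signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, TransformerMixin

from .contexts import CONTEXTS_96, CONTEXT_INDEX, context_key

__all__ = [
    "TrinucleotideCatalog",
    "SignatureMatrix",
    "SignatureExposure",
    "CatalogBuildReport",
    "build_catalog",
    "fit_signatures",
    "call_csig3",
    "call_csig8",
    "SignatureRefitter",
    "synthetic_signature_matrix",
    "RELIABLE_MIN_SNVS",
    "CSIG3_WEIGHT_THRESHOLD",
    "CSIG3_MIN_ATTRIBUTED",
]

#: a catalog supports a reliable signature call when it holds more than this
#: many somatic SNVs
RELIABLE_MIN_SNVS = 50
#: CSig3 call: fitted weight must strictly exceed this fraction of SNVs
CSIG3_WEIGHT_THRESHOLD = 0.20
#: CSig3 call: at least this many mutations must be attributed to CSig3
CSIG3_MIN_ATTRIBUTED = 50


@dataclass(frozen=True)
class TrinucleotideCatalog:
    """96-bin count vector of somatic SNVs for one tumor."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (96,):
            raise ValueError(f"catalog must have exactly 96 bins, got {counts.shape}")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("catalog counts must be finite and non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_snvs(self) -> int:
        return int(round(float(self.counts.sum())))

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError(f"catalog for {self.sample_id} is empty")
        return self.counts / total


@dataclass(frozen=True)
class SignatureMatrix:
    """96 x K reference profiles, one column per signature, columns sum to 1."""

    signature_ids: tuple[str, ...]
    profiles: np.ndarray

    def __post_init__(self):
        ids = tuple(self.signature_ids)
        profiles = np.asarray(self.profiles, dtype=float)
        if profiles.shape != (96, len(ids)):
            raise ValueError(
                f"profiles shape {profiles.shape} inconsistent with {len(ids)} signatures"
            )
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate signature ids")
        if np.any(profiles < 0):
            raise ValueError("signature profiles must be non-negative")
        colsums = profiles.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            bad = [ids[i] for i in np.nonzero(np.abs(colsums - 1.0) > 1e-6)[0]]
            raise ValueError(f"signature columns must sum to 1: {bad}")
        object.__setattr__(self, "signature_ids", ids)
        object.__setattr__(self, "profiles", profiles)

    @property
    def n_signatures(self) -> int:
        return len(self.signature_ids)

    def column(self, signature_id: str) -> np.ndarray:
        return self.profiles[:, self.signature_ids.index(signature_id)]

    def mixture_profile(self, weights: dict[str, float]) -> np.ndarray:
        """96-profile of a weighted signature mixture (weights renormalised)."""
        w = np.zeros(self.n_signatures)
        for name, value in weights.items():
            w[self.signature_ids.index(name)] = value
        if w.sum() <= 0:
            raise ValueError("mixture weights must have positive sum")
        return self.profiles @ (w / w.sum())


@dataclass(frozen=True)
class SignatureExposure:
    """Fitted per-signature weights and signature calls for one tumor."""

    sample_id: str
    signature_ids: tuple[str, ...]
    weights: np.ndarray
    n_snvs: int
    reliable: bool
    csig3_positive: bool
    csig8_positive: bool

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.signature_ids),):
            raise ValueError("weights length must match signature_ids")
        if np.any(w < -1e-12) or w.sum() > 1 + 1e-9:
            raise ValueError("weights must be non-negative with sum <= 1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "signature_ids", tuple(self.signature_ids))

    @property
    def residual_fraction(self) -> float:
        return float(1.0 - self.weights.sum())

    @property
    def attributed_counts(self) -> np.ndarray:
        return self.weights * self.n_snvs

    def weight(self, signature_id: str) -> float:
        if signature_id not in self.signature_ids:
            raise KeyError(f"{signature_id} not in fitted signature set")
        return float(self.weights[self.signature_ids.index(signature_id)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.signature_ids, map(float, self.weights)))


@dataclass
class CatalogBuildReport:
    """Outcome of catalog construction: the catalog plus rejected records."""

    catalog: TrinucleotideCatalog
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def build_catalog(
    sample_id: str,
    snvs: Iterable[tuple],
    context_source: Callable[[str, int], str] | None = None,
) -> CatalogBuildReport:
    """Bin SNVs into a 96-context catalog.

    Each record is ``(chrom, pos, ref, alt)`` or ``(chrom, pos, ref, alt,
    trinucleotide)``.  When the trinucleotide is absent or None, it is
    resolved through ``context_source(chrom, pos)``; without a source this is
    a hard error.  Records that are not single-base substitutions, or whose
    context contains unknown characters, are rejected and reported (never
    silently dropped).
    """
    counts = np.zeros(96)
    rejected: list[tuple[int, str]] = []
    for i, rec in enumerate(snvs):
        if len(rec) == 4:
            chrom, pos, ref, alt = rec
            tri = None
        elif len(rec) >= 5:
            chrom, pos, ref, alt, tri = rec[:5]
        else:
            rejected.append((i, f"malformed record of length {len(rec)}"))
            continue
        if tri is None:
            if context_source is None:
                raise ValueError(
                    f"record {i} ({chrom}:{pos}) has no trinucleotide context and "
                    "no context_source was supplied"
                )
            tri = context_source(chrom, int(pos))
        try:
            key = context_key(str(ref), str(alt), str(tri))
        except ValueError as exc:
            rejected.append((i, str(exc)))
            continue
        counts[CONTEXT_INDEX[key]] += 1
    return CatalogBuildReport(TrinucleotideCatalog(sample_id, counts), rejected)


def _solve_constrained_weights(target: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """Minimise ||target - profiles @ w||^2 s.t. w >= 0, sum(w) <= 1.

    Plain NNLS solves the problem exactly whenever its solution already
    respects the simplex bound (the constraint is then inactive); otherwise
    the bound is active and the program is re-solved with SLSQP from the
    rescaled NNLS point.
    """
    w, _ = optimize.nnls(profiles, target)
    if w.sum() <= 1.0 + 1e-12:
        return w

    def objective(x):
        r = profiles @ x - target
        return 0.5 * float(r @ r)

    def gradient(x):
        return profiles.T @ (profiles @ x - target)

    res = optimize.minimize(
        objective,
        x0=w / w.sum(),
        jac=gradient,
        method="SLSQP",
        bounds=[(0.0, None)] * profiles.shape[1],
        constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum(),
                      "jac": lambda x: -np.ones_like(x)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if not res.success:
        raise RuntimeError(f"signature weight optimisation failed: {res.message}")
    return np.clip(res.x, 0.0, None)


def _apply_cutoff(weights: np.ndarray, cutoff: float) -> np.ndarray:
    """Zero weights below ``cutoff`` and rescale survivors to the pre-cutoff total."""
    total = weights.sum()
    kept = np.where(weights >= cutoff, weights, 0.0)
    if kept.sum() > 0:
        kept = kept * (total / kept.sum())
    return kept


def fit_signatures(
    catalog: TrinucleotideCatalog,
    sigs: SignatureMatrix,
    weight_cutoff: float = 0.06,
    context_scaling: np.ndarray | None = None,
) -> SignatureExposure:
    """Fit one catalog against a signature matrix and apply the signature calls.

    Raises on an empty catalog.  ``csig3_positive`` / ``csig8_positive`` are
    populated when the respective signature id is present in the matrix and
    are False otherwise.

    ``context_scaling``, when given, is a positive 96-vector of per-context
    frequency ratios (e.g. genome/exome trinucleotide abundance) multiplied
    into the catalog before normalisation; by default no such renormalisation
    is applied and catalog and reference are assumed to share a context frame.
    """
    n_snvs = catalog.n_snvs
    if context_scaling is not None:
        scale = np.asarray(context_scaling, dtype=float)
        if scale.shape != (96,) or np.any(scale <= 0):
            raise ValueError("context_scaling must be a positive 96-vector")
        # rescale the fitted profile frame; n_snvs keeps the raw SNV count
        scaled = TrinucleotideCatalog(catalog.sample_id, catalog.counts * scale)
        target = scaled.normalized()
    else:
        target = catalog.normalized()
    weights = _apply_cutoff(
        _solve_constrained_weights(target, sigs.profiles), weight_cutoff
    )
    exposure = SignatureExposure(
        sample_id=catalog.sample_id,
        signature_ids=sigs.signature_ids,
        weights=weights,
        n_snvs=n_snvs,
        reliable=n_snvs > RELIABLE_MIN_SNVS,
        csig3_positive=False,
        csig8_positive=False,
    )
    csig3 = call_csig3(exposure) if "CSig3" in sigs.signature_ids else False
    csig8 = call_csig8(exposure) if "CSig8" in sigs.signature_ids else False
    object.__setattr__(exposure, "csig3_positive", csig3)
    object.__setattr__(exposure, "csig8_positive", csig8)
    return exposure


def call_csig3(exposure: SignatureExposure) -> bool:
    """CSig3 positivity: weight > 0.20, >= 50 attributed mutations, reliable catalog."""
    w = exposure.weight("CSig3")
    return (
        w > CSIG3_WEIGHT_THRESHOLD
        and w * exposure.n_snvs >= CSIG3_MIN_ATTRIBUTED
        and exposure.reliable
    )


def call_csig8(exposure: SignatureExposure) -> bool:
    """CSig8 positivity: weight > 0.20 (no attributed-count floor; see module docs)."""
    return exposure.weight("CSig8") > CSIG3_WEIGHT_THRESHOLD


class SignatureRefitter(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer mapping 96-bin catalogs to signature weights.

    Parameters
    ----------
    signature_matrix : SignatureMatrix, optional
        Reference profiles.  Defaults to :func:`synthetic_signature_matrix`.
    weight_cutoff : float
        Weights below this value are zeroed post-fit and the remaining
        weights rescaled to the pre-cutoff total (default 0.06).

    After :meth:`fit`, ``signature_ids_`` holds the column order of the
    weight matrix returned by :meth:`transform`.
    """

    def __init__(self, signature_matrix: SignatureMatrix | None = None,
                 weight_cutoff: float = 0.06):
        self.signature_matrix = signature_matrix
        self.weight_cutoff = weight_cutoff

    def fit(self, X=None, y=None):
        sigs = self.signature_matrix
        if sigs is None:
            sigs = synthetic_signature_matrix()
        if not isinstance(sigs, SignatureMatrix):
            raise TypeError("signature_matrix must be a SignatureMatrix")
        if not 0.0 <= self.weight_cutoff < 1.0:
            raise ValueError("weight_cutoff must be in [0, 1)")
        self.signature_matrix_ = sigs
        self.signature_ids_ = sigs.signature_ids
        self.n_features_in_ = 96
        return self

    def transform(self, X) -> np.ndarray:
        """Rows of X are 96-bin counts; returns an (n_samples, K) weight matrix."""
        if not hasattr(self, "signature_matrix_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != 96:
            raise ValueError(f"expected 96 context bins, got {X.shape[1]}")
        out = np.empty((X.shape[0], self.signature_matrix_.n_signatures))
        for i, row in enumerate(X):
            total = row.sum()
            if total <= 0:
                raise ValueError(f"row {i} is an empty catalog")
            out[i] = _apply_cutoff(
                _solve_constrained_weights(row / total, self.signature_matrix_.profiles),
                self.weight_cutoff,
            )
        return out


def synthetic_signature_matrix(
    n_signatures: int = 30, seed: int = 715, flat_ids: Sequence[str] = ("CSig3", "CSig8")
) -> SignatureMatrix:
    """Deterministic *synthetic* stand-in for a 30-signature reference matrix.

    This is not the published COSMIC catalogue; it is a synthetic reference
    with the qualitative structure the deconvolution relies on: "CSig1" is a
    spiky C>T-dominated profile (deamination-like), "CSig3" and "CSig8" are
    comparatively flat profiles (as the HRR-deficiency signature famously is),
    and the remaining signatures are sparse random profiles.  Identical
    arguments always yield an identical matrix.  Users with the real COSMIC
    matrix can load it with :func:`ihrdkit.io.read_signature_matrix`.
    """
    if n_signatures < 1:
        raise ValueError("need at least one signature")
    rng = np.random.default_rng(seed)
    ids = tuple(f"CSig{i}" for i in range(1, n_signatures + 1))
    profiles = np.empty((96, n_signatures))
    ct_block = np.array([k.startswith(("A[C>T]", "C[C>T]", "G[C>T]", "T[C>T]"))
                         for k in CONTEXTS_96])
    for j, name in enumerate(ids):
        if name == "CSig1":
            # deamination-like: mass concentrated on C>T contexts
            p = rng.dirichlet(np.full(96, 0.05))
            p[ct_block] += rng.dirichlet(np.full(ct_block.sum(), 0.8)) * 12.0
        elif name in flat_ids:
            # broad, weakly-structured profile (the HRRd signature is famously
            # flat; mild structure keeps it identifiable at exome SNV counts)
            p = rng.dirichlet(np.full(96, 1.0))
        else:
            # sparse, spiky profile
            p = rng.dirichlet(np.full(96, 0.3))
        profiles[:, j] = p / p.sum()
    return SignatureMatrix(ids, profiles)
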