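"""Replica-convergence diagnostics on Cα essential dynamics.

Frames are rigid-body superposed onto a reference, the Cα covariance matrix
is diagonalised, and sampling quality is judged by (i) the essential-subspace
fraction carried by the leading components, (ii) the cosine content of the
projections — a projection indistinguishable from a half-period cosine is
the signature of random-diffusion-like, insufficient sampling — (iii) the
root-mean-square inner product (RMSIP) between the leading eigenvector sets
of two ensembles, and (iv) a pairwise linear-discriminant test: two replicas
whose PC1/PC2 clouds cannot be separated without at least one
misclassification are considered mutually consistent, i.e. concatenable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .io import Ensemble


@dataclass
class PCAModel:
    """Eigendecomposition of the Cα covariance matrix.

    ``eigenvalues`` are in Å², descending; ``eigenvectors`` has shape
    ``(3N, 3N)`` with eigenvectors as rows, orthonormal.
    """

    mean: np.ndarray           # (N_ca, 3) mean structure
    eigenvalues: np.ndarray    # (3N,), descending
    eigenvectors: np.ndarray   # (3N, 3N), rows orthonormal
    ca_indices: list[int]

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


@dataclass
class LDAPairReport:
    labels: tuple[str, str]
    direction: np.ndarray
    misclassified: int
    consistent: bool


@dataclass
class LDAReport:
    pairs: list[LDAPairReport]

    @property
    def all_consistent(self) -> bool:
        return all(p.consistent for p in self.pairs)


@dataclass
class SubspaceReport:
    dimension: int
    es_fraction: float
    rmsip: dict[tuple[str, str], float] = field(default_factory=dict)
    cosine_content: dict[int, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _kabsch(mobile: np.ndarray, ref: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rotation (proper, det +1) and centroids for two point
    sets; returns (R, mobile centroid, ref centroid)."""
    cm = mobile.mean(axis=0)
    cr = ref.mean(axis=0)
    h = (mobile - cm).T @ (ref - cr)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    rot = (u @ flip @ vt)
    return rot, cm, cr


def superpose(ensemble: Ensemble, reference: np.ndarray | None = None
              ) -> Ensemble:
    """Rigid-body least-squares fit of every frame onto the reference.

    The fit is computed on Cα atoms and the resulting rotation/translation
    is applied to all atoms. ``reference`` is a full-atom frame; default is
    the ensemble's first frame. Fewer than 3 Cα raise ``ValueError``.
    """
    ca = ensemble.topology.ca_indices()
    if len(ca) < 3:
        raise ValueError("superposition needs at least 3 Cα atoms")
    if reference is None:
        reference = ensemble.coords[0]
    reference = np.asarray(reference, dtype=float)
    if reference.shape != ensemble.coords[0].shape:
        raise ValueError("reference frame atom count mismatch")
    ref_ca = reference[ca]
    out = np.empty_like(ensemble.coords)
    for f in range(ensemble.n_frames):
        rot, cm, cr = _kabsch(ensemble.coords[f][ca], ref_ca)
        out[f] = (ensemble.coords[f] - cm) @ rot + cr
    return Ensemble(ensemble.topology, out, label=ensemble.label)


# ---------------------------------------------------------------------------
# PCA and essential subspace
# ---------------------------------------------------------------------------

def pca(ensemble: Ensemble) -> PCAModel:
    """Diagonalise the Cα coordinate covariance about the ensemble mean.

    The ensemble is assumed already superposed; the decomposition is a
    symmetric eigendecomposition with eigenvalues in decreasing order.
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    ca = ensemble.topology.ca_indices()
    x = ensemble.coords[:, ca, :].reshape(ensemble.n_frames, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return PCAModel(mean=mean.reshape(-1, 3),
                    eigenvalues=evals[order],
                    eigenvectors=evecs[:, order].T,
                    ca_indices=list(ca))


def essential_fraction(model: PCAModel, dimension: int = 20) -> float:
    """Fraction of total motion in the first ``dimension`` components."""
    if dimension <= 0:
        raise ValueError("dimension must be positive")
    if dimension > model.eigenvalues.size:
        raise ValueError("dimension exceeds the decomposition rank")
    total = model.eigenvalues.sum()
    if total <= 0:
        return 0.0
    # tiny negative eigenvalues from the symmetric solver can push the
    # ratio marginally past 1
    return float(np.clip(model.eigenvalues[:dimension].sum() / total,
                         0.0, 1.0))


def project(ensemble: Ensemble, model: PCAModel, component: int) -> np.ndarray:
    """Per-frame projection of the Cα coordinates onto eigenvector
    ``component`` (0-based), after centring on the model mean."""
    if not 0 <= component < model.eigenvectors.shape[0]:
        raise IndexError(f"component {component} out of range")
    x = ensemble.coords[:, model.ca_indices, :].reshape(ensemble.n_frames, -1)
    return (x - model.mean.ravel()) @ model.eigenvectors[component]


def cosine_content(series: np.ndarray, index: int = 1) -> float:
    """Cosine content c_i of a projection time series.

    c_i = (2/T) (Σ_t cos(iπt/T) p(t) Δt)² / Σ_t p(t)² Δt with uniform unit
    Δt; 1 means the projection is a half-period(×i) cosine — the signature
    of unconverged, diffusion-like sampling — and 0 means orthogonal to it.
    Clamped to [0, 1] against numerical overshoot.
    """
    p = np.asarray(series, dtype=float)
    if p.size < 2:
        raise ValueError("series must have at least 2 samples")
    denom = float(np.sum(p * p))
    if denom <= 0:
        raise ValueError("cosine content undefined for an all-zero series")
    t_len = p.size
    t = np.arange(t_len)
    cos = np.cos(index * np.pi * t / t_len)
    num = (2.0 / t_len) * float(np.sum(cos * p)) ** 2
    return float(np.clip(num / denom, 0.0, 1.0))


def rmsip(basis_a: np.ndarray, basis_b: np.ndarray, dimension: int = 20
          ) -> float:
    """Root-mean-square inner product of two leading eigenvector sets.

    sqrt((1/D) Σ_ij (a_i·b_j)²) over the first D vectors of each basis
    (rows). 1 means identical subspaces, 0 orthogonal ones.
    """
    a = np.asarray(basis_a, dtype=float)
    b = np.asarray(basis_b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("bases have mismatching dimensionality")
    if a.shape[0] < dimension or b.shape[0] < dimension:
        raise ValueError("bases carry fewer vectors than the requested D")
    inner = a[:dimension] @ b[:dimension].T
    return float(np.sqrt(np.sum(inner ** 2) / dimension))


# ---------------------------------------------------------------------------
# LDA replica-consistency test
# ---------------------------------------------------------------------------

def _fisher_ld1(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Fisher discriminant direction for two classes in feature space,
    with ε-regularised within-class scatter when singular."""
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    s_w = ((x1 - m1).T @ (x1 - m1)) + ((x2 - m2).T @ (x2 - m2))
    tr = np.trace(s_w)
    eps = 1e-9 * (tr if tr > 0 else 1.0)
    try:
        w = np.linalg.solve(s_w, m1 - m2)
    except np.linalg.LinAlgError:
        warnings.warn("singular within-class scatter; regularising with eps*I")
        w = np.linalg.solve(s_w + eps * np.eye(s_w.shape[0]), m1 - m2)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def lda_consistency(projections: dict[str, np.ndarray]) -> LDAReport:
    """Pairwise linear-discriminant concatenability test.

    ``projections`` maps replica label to an ``(n_frames, 2)`` array of
    PC1/PC2 projections. For each replica pair a Fisher LD1 is built from
    the two-class between/within scatter; every frame is assigned to the
    nearest class mean on LD1 (equal priors). A pair is *consistent* — the
    replicas sample overlapping regions and may be concatenated — iff at
    least one frame is misclassified; perfect separation flags genuinely
    distinct sampling.
    """
    labels = list(projections)
    if len(labels) < 2:
        raise ValueError("need at least 2 replicas")
    data = {}
    for lab in labels:
        x = np.asarray(projections[lab], dtype=float)
        if x.ndim != 2 or x.shape[0] < 2:
            raise ValueError(f"replica {lab!r} needs >= 2 frames of 2-D "
                             "projections")
        data[lab] = x
    pairs: list[LDAPairReport] = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            x1, x2 = data[la], data[lb]
            w = _fisher_ld1(x1, x2)
            p1, p2 = x1 @ w, x2 @ w
            c1, c2 = p1.mean(), p2.mean()
            mis = int(np.sum(np.abs(p1 - c1) > np.abs(p1 - c2)) +
                      np.sum(np.abs(p2 - c2) > np.abs(p2 - c1)))
            pairs.append(LDAPairReport((la, lb), w, mis, consistent=mis >= 1))
    return LDAReport(pairs)


def replica_diagnostics(ensembles: list[Ensemble], dimension: int = 20,
                        cosine_components: tuple[int, ...] = (1, 2)
                        ) -> tuple[SubspaceReport, LDAReport]:
    """Full convergence block for a replica set.

    Superposes every replica on the first frame of the first replica, runs
    per-replica PCA plus a concatenated PCA, and reports: ES fraction of the
    concatenated decomposition, pairwise RMSIP over the first ``dimension``
    eigenvectors, cosine contents of the concatenated PC projections, and
    the pairwise LDA consistency of the replicas in the concatenated
    PC1/PC2 plane.
    """
    from .io import concatenate

    if not ensembles:
        raise ValueError("no ensembles given")
    ref = ensembles[0].coords[0]
    fitted = [superpose(e, ref) for e in ensembles]
    concat = concatenate(fitted)
    model = pca(concat)
    dim = min(dimension, model.eigenvalues.size)
    per_replica = {e.label: pca(e) for e in fitted}
    report = SubspaceReport(dimension=dim,
                            es_fraction=essential_fraction(model, dim))
    labels = [e.label for e in fitted]
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            report.rmsip[(la, lb)] = rmsip(per_replica[la].eigenvectors,
                                           per_replica[lb].eigenvectors, dim)
    for comp in cosine_components:
        series = project(concat, model, comp - 1)
        report.cosine_content[comp] = cosine_content(series, index=comp)
    projections = {
        e.label: np.column_stack([project(e, model, 0), project(e, model, 1)])
        for e in fitted}
    return report, lda_consistency(projections)
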