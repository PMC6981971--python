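"""Relatedness diagnostics between panels: Rogers distance and marker PCA.

Rogers genetic distance between two populations is, per biallelic locus j
with minor-allele frequencies p_j (population A) and q_j (population B),

    d_j = sqrt(0.5 * sum_alleles (p - q)^2) = |p_j - q_j|,

averaged over loci; it lies in [0, 1], is symmetric, and satisfies the
triangle inequality (it is a mean of per-locus absolute differences).
A line-to-line distance is the same definition with single-line
"populations".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, ValidationError


@dataclass
class DistanceReport:
    label_a: str
    label_b: str
    rogers_distance: float
    n_loci: int
    skipped_loci: list
    per_locus: np.ndarray | None = None


def _shared_freqs(pop_a: GenotypeMatrix, pop_b: GenotypeMatrix):
    shared = [m for m in pop_a.marker_ids if m in set(pop_b.marker_ids)]
    if not shared:
        raise ValidationError("no shared markers between populations")
    ia = {m: j for j, m in enumerate(pop_a.marker_ids)}
    ib = {m: j for j, m in enumerate(pop_b.marker_ids)}
    da = pop_a.dosage_float()[:, [ia[m] for m in shared]]
    db = pop_b.dosage_float()[:, [ib[m] for m in shared]]
    # express population B in A's allele orientation
    mismatch = pop_b.flipped[[ib[m] for m in shared]] ^ pop_a.flipped[[ia[m] for m in shared]]
    db[:, mismatch] = 2.0 - db[:, mismatch]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p = np.nanmean(da, axis=0) / 2.0  # NaN where a locus is fully missing
        q = np.nanmean(db, axis=0) / 2.0
    return np.asarray(shared, dtype=object), p, q


def rogers_distance(pop_a: GenotypeMatrix, pop_b: GenotypeMatrix,
                    label_a: str = "A", label_b: str = "B",
                    keep_per_locus: bool = False) -> DistanceReport:
    """Mean per-locus Rogers distance between two panels on shared markers.

    Loci where either population has no non-missing call are skipped and
    listed in the report; if every locus is skipped an error is raised.
    """
    shared, p, q = _shared_freqs(pop_a, pop_b)
    ok = np.isfinite(p) & np.isfinite(q)
    skipped = shared[~ok].tolist()
    if not ok.any():
        raise ValidationError("every shared locus lacks calls in one population")
    d = np.abs(p[ok] - q[ok])  # sqrt(0.5*((p-q)^2+(q-p)^2)) for 2 alleles
    return DistanceReport(
        label_a=label_a, label_b=label_b,
        rogers_distance=float(d.mean()),
        n_loci=int(ok.sum()), skipped_loci=skipped,
        per_locus=d if keep_per_locus else None,
    )


def marker_pca(g: GenotypeMatrix, n_components: int = 2,
               scale: bool = False) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the centered dosage matrix via SVD.

    Returns (scores indexed by line, explained-variance fractions).
    Missing calls must be imputed first; centering is by marker mean, with
    optional unit-variance scaling of markers.
    """
    if n_components > min(g.n_lines, g.n_markers):
        raise ValueError("n_components exceeds min(lines, markers)")
    d = g.dosage_float()
    if np.isnan(d).any():
        raise ValidationError("missing calls present; run impute_missing first")
    M = d - d.mean(axis=0)[None, :]
    if scale:
        sd = M.std(axis=0)
        sd[sd == 0] = 1.0
        M = M / sd[None, :]
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = U[:, :n_components] * s[:n_components]
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=list(g.line_ids), columns=cols), frac[:n_components]
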