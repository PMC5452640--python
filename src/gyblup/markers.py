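"""Marker coding, quality control, kinship cross-products and marker-space diagnostics.

Markers enter as raw biallelic calls (``"AA"``, ``"BB"``, ``"AB"``, ``"NA"``,
``"FAIL"``) or as an already coded genotype x marker matrix with entries in
{-1, 0, 1}.  Homozygous classes are coded -1/+1, heterozygous calls, missing
values and technical failures are coded 0.  The minor-allele homozygote maps
to +1 (ties broken towards the lexicographically smaller allele symbol); the
choice of sign is irrelevant to every downstream variance, which only ever
sees cross-products ``Z Z^T``.

No kinship normalisation is applied: the ridge formulation of the prediction
models uses the raw cross-product with a single variance parameter, so any
scaling would simply be absorbed by that parameter.  ``cross_products``
exposes an optional ``scale`` flag for users who want a per-marker average.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

MISSING_CODES = {"NA", "FAIL", "", "NN", None}

__all__ = [
    "code_markers",
    "qc_filter",
    "cross_products",
    "pca_scores",
    "mean_euclidean_distance",
    "read_marker_matrix",
    "write_marker_matrix",
    "read_raw_calls",
]


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or str(v).upper() in MISSING_CODES


def _column_alleles(col: pd.Series, marker: str):
    """Split one raw-call column into per-genotype (allele1, allele2) or None for missing."""
    pairs = []
    alleles = set()
    for v in col:
        if _is_missing(v):
            pairs.append(None)
            continue
        s = str(v).strip().upper()
        if len(s) != 2:
            raise ValueError(f"marker {marker!r}: call {v!r} is not a two-allele string")
        pairs.append((s[0], s[1]))
        alleles.update(s)
    if len(alleles) > 2:
        raise ValueError(
            f"marker {marker!r} references {len(alleles)} allele symbols "
            f"({sorted(alleles)}); at most two are allowed"
        )
    return pairs, alleles


def _allele_stats(pairs, alleles):
    """Allele frequency bookkeeping for one marker column.

    Returns (freq by allele over called gametes, n_called, n_missing, n_het).
    """
    counts = {a: 0 for a in alleles}
    n_called = 0
    n_missing = 0
    n_het = 0
    for p in pairs:
        if p is None:
            n_missing += 1
            continue
        n_called += 1
        counts[p[0]] += 1
        counts[p[1]] += 1
        if p[0] != p[1]:
            n_het += 1
    freq = {a: (c / (2 * n_called) if n_called else np.nan) for a, c in counts.items()}
    return freq, n_called, n_missing, n_het


def _plus_allele(freq: dict) -> str | None:
    """Allele assigned to +1: the minor allele, ties to the lexicographically smaller symbol.

    A monomorphic marker has no minor allele; its sole (major) allele codes -1.
    """
    if len(freq) == 1:
        return None
    return sorted(freq.items(), key=lambda kv: (kv[1], kv[0]))[0][0]


def code_markers(raw: pd.DataFrame) -> pd.DataFrame:
    """Code raw biallelic calls to the {-1, 0, 1} marker matrix.

    Per marker the two homozygous classes map to -1 and +1 (minor-allele
    homozygote to +1) while heterozygous, missing and failed calls map to 0.
    Markers with more than two allele symbols are rejected.
    """
    if raw.index.has_duplicates:
        raise ValueError("duplicate genotype ids in raw calls")
    out = np.zeros((raw.shape[0], raw.shape[1]), dtype=np.int8)
    for j, marker in enumerate(raw.columns):
        pairs, alleles = _column_alleles(raw.iloc[:, j], marker)
        if not alleles:
            continue
        freq, *_ = _allele_stats(pairs, alleles)
        plus = _plus_allele(freq)
        for i, p in enumerate(pairs):
            if p is None or p[0] != p[1]:
                continue
            out[i, j] = 1 if p[0] == plus else -1
    return pd.DataFrame(out, index=raw.index.copy(), columns=raw.columns.copy())


def qc_filter(
    calls: pd.DataFrame,
    maf_min: float = 0.01,
    max_missing: float = 0.10,
):
    """Drop monomorphic, low-MAF and high-missingness markers.

    ``calls`` may be raw symbolic calls (preferred: allele frequencies then
    count heterozygotes as one copy of each allele and the missing fraction
    counts only NA/FAIL) or a coded matrix (zeros treated as non-informative:
    MAF from the +/-1 entries, zero fraction used as the missingness proxy).

    Returns ``(Z, report)`` where ``Z`` is the coded matrix restricted to the
    surviving markers and ``report`` is a per-marker table with columns
    ``maf``, ``missing``, ``kept`` and ``reason``.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")

    is_coded = all(pd.api.types.is_numeric_dtype(dt) for dt in calls.dtypes)
    rows = []
    for j, marker in enumerate(calls.columns):
        col = calls.iloc[:, j]
        if is_coded:
            vals = col.to_numpy(dtype=float)
            n_plus = int(np.sum(vals == 1))
            n_minus = int(np.sum(vals == -1))
            n_called = n_plus + n_minus
            p = n_plus / n_called if n_called else np.nan
            maf = min(p, 1 - p) if n_called else np.nan
            missing = float(np.mean(vals == 0))
            polymorphic = n_plus > 0 and n_minus > 0
        else:
            pairs, alleles = _column_alleles(col, marker)
            freq, n_called, n_missing, n_het = _allele_stats(pairs, alleles)
            missing = n_missing / len(pairs)
            maf = min(freq.values()) if len(freq) == 2 and n_called else 0.0
            # a single allele symbol, or one homozygote class plus nothing else
            polymorphic = len(alleles) == 2 and n_called > 0 and maf > 0
        if not polymorphic or (maf is not np.nan and np.isnan(maf)):
            reason = "monomorphic"
            kept = False
        elif missing > max_missing:
            reason = "missing"
            kept = False
        elif maf < maf_min:
            reason = "maf"
            kept = False
        else:
            reason = ""
            kept = True
        rows.append((marker, maf, missing, kept, reason))

    report = pd.DataFrame(rows, columns=["marker", "maf", "missing", "kept", "reason"])
    report = report.set_index("marker")
    keep = report.index[report["kept"]]
    if len(keep) == 0:
        counts = report["reason"].value_counts()
        raise ValueError(f"no markers survive QC (dropped: {counts.to_dict()})")
    Z = calls if is_coded else code_markers(calls)
    return Z.loc[:, keep].astype(np.int8, errors="ignore"), report


def _check_ids(Z: pd.DataFrame, ids) -> pd.Index:
    ids = pd.Index(ids)
    missing = ids.difference(Z.index)
    if len(missing):
        raise KeyError(f"genotypes without marker rows: {sorted(map(str, missing))}")
    return ids


def cross_products(Z: pd.DataFrame, rows_a, rows_b, scale: bool = False) -> np.ndarray:
    """Marker cross-product block ``Z_a Z_b^T`` (the raw-kinship cross block).

    With ``rows_a == rows_b`` this is the symmetric PSD kinship of the ridge
    formulation.  ``scale=True`` divides by the marker count.
    """
    a = _check_ids(Z, rows_a)
    b = _check_ids(Z, rows_b)
    out = Z.loc[a].to_numpy(float) @ Z.loc[b].to_numpy(float).T
    if scale:
        out /= Z.shape[1]
    return out


def pca_scores(Z: pd.DataFrame, k: int):
    """Principal-component scores of the column-centered marker matrix.

    Centering only, no column scaling (standard marker PCA).  Returns
    ``(scores, var_explained)``; variance shares are non-increasing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n, m = Z.shape
    if k > min(n - 1, m):
        raise ValueError(f"k={k} exceeds min(n_genotypes - 1, n_markers) = {min(n - 1, m)}")
    X = Z.to_numpy(float)
    X = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * s[:k]
    var = s**2
    var_explained = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    return (
        pd.DataFrame(scores, index=Z.index, columns=[f"PC{i + 1}" for i in range(k)]),
        var_explained,
    )


def mean_euclidean_distance(Z_ts: pd.DataFrame, Z_vs: pd.DataFrame) -> float:
    """Mean Euclidean distance over all TS x VS genotype pairs (TS-VS relatedness summary)."""
    if list(Z_ts.columns) != list(Z_vs.columns):
        raise ValueError("marker columns of the two matrices do not match")
    d = cdist(Z_ts.to_numpy(float), Z_vs.to_numpy(float))
    return float(d.mean())


# ---------------------------------------------------------------------------
# delimited-text I/O: first column genotype id, header row of marker ids


def read_marker_matrix(path, sep: str = "\t") -> pd.DataFrame:
    Z = pd.read_csv(path, sep=sep, index_col=0)
    bad = set(np.unique(Z.to_numpy())) - {-1, 0, 1}
    if bad:
        raise ValueError(f"coded marker file contains values outside {{-1,0,1}}: {sorted(bad)}")
    return Z.astype(np.int8)


def write_marker_matrix(Z: pd.DataFrame, path, sep: str = "\t") -> None:
    Z.to_csv(path, sep=sep, index_label="genotype")


def read_raw_calls(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
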