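"""Genomic relationship matrices for additive, dominance, and imprinting effects.

Four kinds are supported, each a cross-product of per-locus design codes
pooled over markers and scaled by the summed per-locus code variance
expected under Hardy-Weinberg proportions (p = alt frequency, q = 1 - p):

====== ===================================== =====================================
kind   code matrix W (per marker k)          scaling constant c
====== ===================================== =====================================
A      Z_k - 2 p_k   (genotypic additive)    sum_k 2 p_k q_k
D      H_k - 2 p_k q_k (genotypic dominance) sum_k 2 p_k q_k (1 - 2 p_k q_k)
P      S_k (imprinting contrast, uncentered) sum_k 2 p_k q_k
Dstar  NOIA dominance-deviation code         sum_k (2 p_k q_k)^2
====== ===================================== =====================================

with GRM = W W' / c.  {A, D, P} parameterize the genotypic decomposition;
{A, Dstar, P} the classical breeding-value / dominance-deviation one.
Markers should be pre-filtered to MAF >= 0.01 before building GRMs.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import eigvalsh

from .coding import CodedMatrix

KINDS = ("A", "D", "P", "Dstar")

#: relative tolerance for the smallest admissible (negative) eigenvalue
PSD_RTOL = 1e-8


@dataclass
class GRM:
    """Symmetric n x n genomic relationship matrix of a given kind."""

    matrix: np.ndarray
    kind: str
    n_markers: int
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square")
        if self.sample_ids and len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match GRM dimension")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)  # exact symmetry

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def subset(self, ids: list[str]) -> "GRM":
        index = {s: k for k, s in enumerate(self.sample_ids)}
        rows = np.array([index[s] for s in ids])
        return GRM(self.matrix[np.ix_(rows, rows)], self.kind, self.n_markers, list(ids))

    def block(self, row_ids: list[str], col_ids: list[str]) -> np.ndarray:
        """Rectangular cross-relationship block (e.g. new x training)."""
        index = {s: k for k, s in enumerate(self.sample_ids)}
        r = np.array([index[s] for s in row_ids])
        c = np.array([index[s] for s in col_ids])
        return self.matrix[np.ix_(r, c)]


def _code_matrix(coded: CodedMatrix, kind: str) -> tuple[np.ndarray, float]:
    """Return (W, c) such that GRM = W W' / c for the requested kind."""
    p = coded.p
    q = 1.0 - p
    het = 2.0 * p * q
    if kind == "A":
        if coded.scheme == "genotypic":
            W = coded.Z - 2.0 * p
        elif coded.scheme in ("centered", "noia"):
            W = coded.Z  # already the centered additive code
        else:  # pragma: no cover
            raise ValueError(f"unsupported scheme {coded.scheme}")
        c = float(np.sum(het))
    elif kind == "D":
        if coded.scheme != "genotypic":
            raise ValueError("kind 'D' requires genotypic-scheme dominance codes")
        W = coded.H - het
        c = float(np.sum(het * (1.0 - het)))
    elif kind == "P":
        W = coded.S
        c = float(np.sum(het))
    elif kind == "Dstar":
        if coded.scheme != "noia":
            raise ValueError("kind 'Dstar' requires noia-scheme dominance codes")
        W = coded.H
        c = float(np.sum(het**2))
    else:
        raise ValueError(f"unknown GRM kind {kind!r}; choose from {KINDS}")
    if c <= 0.0:
        raise ValueError(
            f"zero scaling constant for kind {kind!r}: all markers monomorphic?"
        )
    return np.ascontiguousarray(W, dtype=float), c


def build_grm(coded: CodedMatrix, kind: str) -> GRM:
    """Build a GRM of the requested kind from coded genotypes.

    Kinds A, D, P use the genotypic coding scheme (the 2p / 2pq shifts are
    applied internally); Dstar uses the NOIA dominance-deviation codes.
    """
    W, c = _code_matrix(coded, kind)
    M = (W @ W.T) / c
    return GRM(M, kind, coded.n_variants, list(coded.sample_ids))


def build_grms(coded: CodedMatrix, kinds: tuple[str, ...] = ("A", "D", "P")) -> list[GRM]:
    return [build_grm(coded, k) for k in kinds]


def grm_diagnostics(g: GRM, psd_rtol: float = PSD_RTOL) -> dict:
    """Summary diagnostics: diagonal mean, off-diagonal summary, min eigenvalue.

    Warns when the matrix is indefinite beyond ``psd_rtol`` times its
    largest eigenvalue.
    """
    M = g.matrix
    n = g.n
    diag = np.diag(M)
    if n > 1:
        off = M[~np.eye(n, dtype=bool)]
        off_summary = dict(
            mean=float(off.mean()), min=float(off.min()), max=float(off.max())
        )
    else:
        off_summary = dict(mean=0.0, min=0.0, max=0.0)
    lo = float(eigvalsh(M, subset_by_index=[0, 0])[0])
    hi = float(eigvalsh(M, subset_by_index=[n - 1, n - 1])[0])
    psd_ok = lo >= -psd_rtol * max(hi, 1.0)
    if not psd_ok:
        warnings.warn(
            f"GRM kind {g.kind} indefinite: min eigenvalue {lo:.3e} "
            f"(largest {hi:.3e})",
            stacklevel=2,
        )
    return dict(
        kind=g.kind,
        n=n,
        n_markers=g.n_markers,
        mean_diagonal=float(diag.mean()),
        min_diagonal=float(diag.min()),
        max_diagonal=float(diag.max()),
        offdiag=off_summary,
        min_eigenvalue=lo,
        max_eigenvalue=hi,
        psd_ok=bool(psd_ok),
    )


# ---------------------------------------------------------------------------
# GCTA binary GRM format and plain-text TSV
# ---------------------------------------------------------------------------

def write_grm_gcta(g: GRM, prefix: str | Path) -> None:
    """Write grm.bin / grm.N.bin / grm.id triplet (GCTA binary format).

    Lower-triangle (row-major, including diagonal) float32 values; marker
    counts as float32; ids as two-column text (family id repeated).
    """
    prefix = Path(prefix)
    n = g.n
    tri = g.matrix[np.tril_indices(n)]
    with open(f"{prefix}.grm.bin", "wb") as fh:
        fh.write(tri.astype("<f4").tobytes())
    with open(f"{prefix}.grm.N.bin", "wb") as fh:
        fh.write(np.full(tri.size, g.n_markers, dtype="<f4").tobytes())
    with open(f"{prefix}.grm.id", "w") as fh:
        for s in g.sample_ids:
            fh.write(f"{s}\t{s}\n")


def read_grm_gcta(prefix: str | Path, kind: str = "A") -> GRM:
    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(f"{prefix}.grm.id")]
    n = len(ids)
    tri = np.frombuffer(open(f"{prefix}.grm.bin", "rb").read(), dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise ValueError(f"{prefix}.grm.bin has wrong size for {n} ids")
    counts = np.frombuffer(open(f"{prefix}.grm.N.bin", "rb").read(), dtype="<f4")
    M = np.zeros((n, n))
    M[np.tril_indices(n)] = tri
    M = M + np.tril(M, -1).T
    return GRM(M, kind, int(round(float(counts[0]))), ids)


def write_grm_tsv(g: GRM, path: str | Path) -> None:
    df = pd.DataFrame(g.matrix, index=g.sample_ids, columns=g.sample_ids)
    df.index.name = f"grm_{g.kind}_m{g.n_markers}"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_grm_tsv(path: str | Path) -> GRM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    name = str(df.index.name or "")
    kind, n_markers = "A", 0
    if name.startswith("grm_"):
        parts = name.split("_")
        kind = parts[1]
        if len(parts) > 2 and parts[2].startswith("m"):
            n_markers = int(parts[2][1:])
    return GRM(df.to_numpy(), kind, n_markers, [str(s) for s in df.index])
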