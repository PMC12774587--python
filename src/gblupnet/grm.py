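"""Genomic relationship matrices: additive G, dominance D, epistatic E_aa.

G follows VanRaden method 1 (centered dosages with a single global
denominator sum 2 p_k (1 - p_k)).  D uses the heterozygosity coding of Zhu
et al. (z = 1 for heterozygotes), with per-marker denominator 2 p_k^2 q_k^2
averaged over markers.  E_aa is the Hadamard square of G scaled by
v = tr(G o G) / n so that its trace equals the number of individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


@dataclass
class RelationshipMatrix:
    values: np.ndarray
    kind: str  # additive | dominance | epistatic
    n_markers_used: int
    individual_ids: list[str] = field(default=None)
    scaling_factor_v: float | None = None  # epistatic only

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        if self.kind not in ("additive", "dominance", "epistatic"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.individual_ids is None:
            self.individual_ids = [f"id{i + 1}" for i in range(n)]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.individual_ids, columns=self.individual_ids).to_csv(path)


def allele_frequencies(genotypes: GenotypeMatrix) -> np.ndarray:
    """Reference-allele frequency p_k = (dosage sum at k) / 2n per marker."""
    X = genotypes.dosages
    p = X.sum(axis=0) / (2.0 * X.shape[0])
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic marker encountered; run QC before building matrices")
    return p


def build_G(genotypes: GenotypeMatrix, frequencies: np.ndarray | None = None) -> RelationshipMatrix:
    """Additive GRM: G = W W' / sum_k 2 p_k (1 - p_k), with W = T - 2p."""
    if frequencies is None:
        frequencies = allele_frequencies(genotypes)
    p = np.asarray(frequencies, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must be strictly inside (0, 1)")
    W = genotypes.dosages.astype(float) - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom == 0:
        raise ValueError("zero denominator: all markers monomorphic")
    G = (W @ W.T) / denom
    return RelationshipMatrix(
        values=G, kind="additive", n_markers_used=genotypes.n_markers,
        individual_ids=list(genotypes.individual_ids),
    )


def build_D(genotypes: GenotypeMatrix, frequencies: np.ndarray | None = None) -> RelationshipMatrix:
    """Dominance GRM with heterozygosity coding.

    D_ij = (1/m) sum_k (z_ik - 2 p_k q_k)(z_jk - 2 p_k q_k) / (2 p_k^2 q_k^2),
    z = 1 for heterozygotes and 0 otherwise.
    """
    if frequencies is None:
        frequencies = allele_frequencies(genotypes)
    p = np.asarray(frequencies, dtype=float)
    q = 1.0 - p
    denom = 2.0 * p**2 * q**2
    if np.any(denom == 0):
        raise ValueError("zero per-marker denominator in dominance matrix")
    Z = (genotypes.dosages == 1).astype(float) - 2.0 * p * q
    Zs = Z / np.sqrt(denom)
    D = (Zs @ Zs.T) / genotypes.n_markers
    return RelationshipMatrix(
        values=D, kind="dominance", n_markers_used=genotypes.n_markers,
        individual_ids=list(genotypes.individual_ids),
    )


def build_Eaa(G: RelationshipMatrix) -> RelationshipMatrix:
    """Additive-by-additive epistatic GRM: E_aa = (G o G) / v, v = tr(G o G)/n."""
    if G.kind != "additive":
        raise ValueError("E_aa must be built from an additive relationship matrix")
    GG = G.values * G.values
    v = float(np.trace(GG)) / G.n
    if v == 0:
        raise ValueError("scaling factor v is zero (all-zero G)")
    return RelationshipMatrix(
        values=GG / v, kind="epistatic", n_markers_used=G.n_markers_used,
        individual_ids=list(G.individual_ids), scaling_factor_v=v,
    )


def write_grm_bin(grm: RelationshipMatrix, prefix: str) -> list[str]:
    """Write in the GCTA GRM-bin convention.

    ``<prefix>.grm.bin`` holds the lower triangle (diagonal included) as
     32-bit floats in row-major order, ``<prefix>.grm.N.bin`` the per-pair
    marker count, and ``<prefix>.grm.id`` a two-column id text file.
    """
    n = grm.n
    idx = np.tril_indices(n)
    tri = grm.values[idx].astype(np.float32)
    paths = [f"{prefix}.grm.bin", f"{prefix}.grm.N.bin", f"{prefix}.grm.id"]
    tri.tofile(paths[0])
    np.full(tri.shape, grm.n_markers_used, dtype=np.float32).tofile(paths[1])
    with open(paths[2], "w") as fh:
        for iid in grm.individual_ids:
            fh.write(f"0\t{iid}\n")
    return paths


def read_grm_bin(prefix: str, kind: str = "additive") -> RelationshipMatrix:
    """Read a GCTA-convention binary GRM written by :func:`write_grm_bin`."""
    with open(f"{prefix}.grm.id") as fh:
        ids = [line.split()[1] for line in fh if line.strip()]
    n = len(ids)
    tri = np.fromfile(f"{prefix}.grm.bin", dtype=np.float32)
    if tri.size != n * (n + 1) // 2:
        raise ValueError("GRM triangle size does not match id file")
    vals = np.zeros((n, n))
    idx = np.tril_indices(n)
    vals[idx] = tri
    vals = vals + vals.T - np.diag(np.diag(vals))
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype=np.float32)
    return RelationshipMatrix(
        values=vals, kind=kind, n_markers_used=int(counts[0]) if counts.size else 0,
        individual_ids=ids,
    )
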