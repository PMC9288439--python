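"""Square r-squared linkage-disequilibrium matrices over ordered SNP lists."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["LdMatrix", "read_ld_matrix", "write_ld_matrix"]


class LdMatrix:
    """Symmetric matrix of squared allelic correlations (r^2) for one region.

    Entries lie in [0, 1]; the diagonal is 1; symmetry is enforced within
    1e-12 at construction.
    """

    def __init__(self, snp_ids, r2):
        self.snp_ids = [str(s) for s in snp_ids]
        r2 = np.asarray(r2, dtype=float)
        if r2.ndim != 2 or r2.shape[0] != r2.shape[1]:
            raise ValueError("r2 must be a square matrix")
        if r2.shape[0] != len(self.snp_ids):
            raise ValueError("snp_ids length does not match matrix size")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids in LD matrix")
        if np.max(np.abs(r2 - r2.T)) > 1e-12:
            raise ValueError("r2 matrix is not symmetric")
        if np.any((r2 < -1e-12) | (r2 > 1 + 1e-12)):
            raise ValueError("r2 entries must lie in [0, 1]")
        if np.max(np.abs(np.diag(r2) - 1)) > 1e-12:
            raise ValueError("r2 diagonal must be 1")
        self.r2 = np.clip((r2 + r2.T) / 2.0, 0.0, 1.0)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __len__(self) -> int:
        return len(self.snp_ids)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"SNP {exc.args[0]} absent from LD matrix") from None

    def submatrix(self, snp_ids) -> "LdMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LdMatrix(list(snp_ids), self.r2[np.ix_(idx, idx)])

    @classmethod
    def block_diagonal(cls, blocks: list["LdMatrix"]) -> "LdMatrix":
        """Combine per-region matrices; across-block r^2 is 0."""
        ids = [s for b in blocks for s in b.snp_ids]
        n = len(ids)
        full = np.zeros((n, n))
        off = 0
        for b in blocks:
            m = len(b)
            full[off:off + m, off:off + m] = b.r2
            off += m
        return cls(ids, full)


def read_ld_matrix(path) -> LdMatrix:
    """Read an LD matrix file.

    Two layouts are accepted: (a) first line whitespace-separated SNP ids
    followed by a square numeric matrix; (b) long format with a
    ``SNP_A SNP_B R2`` header (unlisted pairs default to r^2 = 0).
    """
    with open(path) as fh:
        first = fh.readline().split()
    if [t.upper() for t in first[:3]] == ["SNP_A", "SNP_B", "R2"]:
        df = pd.read_csv(path, sep=r"\s+")
        ids = sorted(set(df["SNP_A"]) | set(df["SNP_B"]))
        index = {s: i for i, s in enumerate(ids)}
        r2 = np.eye(len(ids))
        for a, b, v in zip(df["SNP_A"], df["SNP_B"], df["R2"]):
            i, j = index[a], index[b]
            r2[i, j] = r2[j, i] = float(v)
        return LdMatrix(ids, r2)
    mat = np.loadtxt(path, skiprows=1)
    if mat.ndim == 1:
        mat = mat.reshape(1, 1)
    return LdMatrix(first, mat)


def write_ld_matrix(ld: LdMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(ld.snp_ids) + "\n")
        np.savetxt(fh, ld.r2, fmt="%.10g")
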