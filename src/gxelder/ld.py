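"""Block LD matrices, eigen-decomposition, and Z-score whitening.

The estimators in this package regress transformed summary statistics on LD
eigenvalues.  Within each approximately independent genomic block the LD
(Pearson correlation) matrix ``R`` is eigen-decomposed as ``R = U D Uᵀ`` and
Z-score vectors are whitened as ``z̃ = D^(-1/2) Uᵀ z``, which de-correlates
the per-variant statistics and exposes one moment condition per retained
eigencomponent.

Eigenvalues below ``tol * max(D)`` are truncated: ``D^(-1/2)`` explodes on
near-null components and they carry essentially no information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LDBlock",
    "EigenBlock",
    "LDReference",
    "compute_block_ld",
    "eigendecompose",
    "transform_z",
    "make_ld_reference",
    "blocks_from_regions",
    "chunk_variants",
]

_SYM_TOL = 1e-8
DEFAULT_EIGEN_TOL = 1e-6


@dataclass
class LDBlock:
    """One genomic block's variant list and LD correlation matrix."""

    block_id: int
    variant_ids: list[str]
    R: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        m = len(self.variant_ids)
        if self.R.shape != (m, m):
            raise ValueError(
                f"block {self.block_id}: R shape {self.R.shape} does not match "
                f"{m} variants"
            )
        if not np.allclose(self.R, self.R.T, atol=_SYM_TOL):
            raise ValueError(f"block {self.block_id}: R is not symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-6):
            raise ValueError(f"block {self.block_id}: R diagonal is not unit")

    @property
    def dim(self) -> int:
        return self.R.shape[0]


@dataclass
class EigenBlock:
    """Truncated eigen-decomposition of one block's LD matrix.

    ``eigenvalues`` are the retained eigenvalues in non-increasing order and
    ``U`` holds the matching orthonormal eigenvectors as columns
    (``original_dim x retained_rank``).
    """

    block_id: int
    variant_ids: list[str]
    eigenvalues: np.ndarray
    U: np.ndarray
    original_dim: int = field(default=0)

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        if self.original_dim == 0:
            self.original_dim = self.U.shape[0]
        if np.any(self.eigenvalues <= 0):
            raise ValueError("retained eigenvalues must be strictly positive")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted in non-increasing order")

    @property
    def retained_rank(self) -> int:
        return int(self.eigenvalues.shape[0])

    def ld_scores(self) -> np.ndarray:
        """Per-variant LD scores, the diagonal of R² = U D² Uᵀ.

        Exact when no eigenvalue was truncated; with truncation the dropped
        mass is numerically negligible by construction.
        """
        return (self.U**2) @ (self.eigenvalues**2)

    def reconstruct(self) -> np.ndarray:
        """U D Uᵀ over retained components."""
        return (self.U * self.eigenvalues) @ self.U.T


def compute_block_ld(
    genotypes: np.ndarray,
    variant_ids: Sequence[str] | None = None,
    block_id: int = 0,
) -> LDBlock:
    """Sample Pearson correlation matrix of an ``n x m`` dosage matrix."""
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("genotypes must be an n x m matrix with m >= 1")
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(X.shape[1])]
    if bad.size:
        raise ValueError(
            f"zero-variance genotype column(s): {[variant_ids[j] for j in bad]}"
        )
    Xs = (X - X.mean(axis=0)) / sd
    R = (Xs.T @ Xs) / X.shape[0]
    # exact unit diagonal / symmetry against round-off
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    np.clip(R, -1.0, 1.0, out=R)
    return LDBlock(block_id=block_id, variant_ids=list(variant_ids), R=R)


def eigendecompose(block: LDBlock, tol: float = DEFAULT_EIGEN_TOL) -> EigenBlock:
    """Eigen-decompose an LD block and truncate near-null components.

    Components with eigenvalue ``<= tol * max(eigenvalue)`` are dropped.
    Each retained eigenvector is signed so its largest-magnitude element is
    positive, giving reproducible output across linear-algebra backends.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if not np.allclose(block.R, block.R.T, atol=_SYM_TOL):
        raise ValueError("LD matrix is not symmetric")
    w, V = np.linalg.eigh(block.R)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    cutoff = tol * max(w[0], 0.0)
    keep = w > max(cutoff, 0.0)
    w, V = w[keep], V[:, keep]
    if w.size == 0:
        raise ValueError(f"block {block.block_id}: no eigenvalue above tolerance")
    # deterministic eigenvector sign
    flip = V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])] < 0
    V[:, flip] *= -1.0
    return EigenBlock(
        block_id=block.block_id,
        variant_ids=list(block.variant_ids),
        eigenvalues=w,
        U=V,
        original_dim=block.dim,
    )


def transform_z(eb: EigenBlock, z: np.ndarray) -> np.ndarray:
    """Whiten a Z-score vector: ``D^(-1/2) Uᵀ z`` over retained components."""
    z = np.asarray(z, dtype=float)
    if z.shape != (eb.original_dim,):
        raise ValueError(
            f"z has length {z.shape[0] if z.ndim == 1 else z.shape}, "
            f"expected {eb.original_dim}"
        )
    return (eb.U.T @ z) / np.sqrt(eb.eigenvalues)


# ---------------------------------------------------------------------------
# LD reference container


@dataclass
class LDReference:
    """An ordered collection of eigen-decomposed LD blocks.

    ``ld_blocks`` optionally retains the raw correlation matrices so the
    reference can be subset to a smaller variant set (which requires
    re-decomposition).
    """

    eigenblocks: list[EigenBlock]
    ld_blocks: list[LDBlock] | None = None
    tol: float = DEFAULT_EIGEN_TOL

    @property
    def variant_ids(self) -> list[str]:
        out: list[str] = []
        for eb in self.eigenblocks:
            out.extend(eb.variant_ids)
        return out

    @property
    def n_variants(self) -> int:
        return sum(eb.original_dim for eb in self.eigenblocks)

    def ld_scores(self) -> np.ndarray:
        return np.concatenate([eb.ld_scores() for eb in self.eigenblocks])

    def subset(self, variant_ids: Iterable[str]) -> "LDReference":
        """Restrict the reference to ``variant_ids`` (order preserved per block).

        Requires the raw correlation matrices; blocks left empty are dropped.
        """
        if self.ld_blocks is None:
            raise ValueError(
                "cannot subset an LD reference without stored correlation "
                "matrices; rebuild with keep_r=True"
            )
        wanted = set(variant_ids)
        new_eigen, new_blocks = [], []
        for blk in self.ld_blocks:
            idx = [j for j, v in enumerate(blk.variant_ids) if v in wanted]
            if not idx:
                continue
            sub = LDBlock(
                block_id=blk.block_id,
                variant_ids=[blk.variant_ids[j] for j in idx],
                R=blk.R[np.ix_(idx, idx)],
            )
            new_blocks.append(sub)
            new_eigen.append(eigendecompose(sub, tol=self.tol))
        if not new_eigen:
            raise ValueError("subset leaves no variants in the LD reference")
        return LDReference(eigenblocks=new_eigen, ld_blocks=new_blocks, tol=self.tol)

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write one array container per block plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"tol": self.tol, "blocks": []}
        raw = {b.block_id: b for b in (self.ld_blocks or [])}
        for eb in self.eigenblocks:
            fname = f"block_{eb.block_id}.npz"
            arrays = {"eigenvalues": eb.eigenvalues, "U": eb.U}
            if eb.block_id in raw:
                arrays["R"] = raw[eb.block_id].R
            np.savez(directory / fname, **arrays)
            manifest["blocks"].append(
                {
                    "block_id": eb.block_id,
                    "file": fname,
                    "variant_ids": eb.variant_ids,
                    "original_dim": eb.original_dim,
                    "retained_rank": eb.retained_rank,
                }
            )
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "LDReference":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        eigenblocks, ld_blocks = [], []
        for entry in manifest["blocks"]:
            with np.load(directory / entry["file"]) as data:
                eb = EigenBlock(
                    block_id=entry["block_id"],
                    variant_ids=list(entry["variant_ids"]),
                    eigenvalues=data["eigenvalues"],
                    U=data["U"],
                    original_dim=entry["original_dim"],
                )
                if "R" in data:
                    ld_blocks.append(
                        LDBlock(
                            block_id=entry["block_id"],
                            variant_ids=list(entry["variant_ids"]),
                            R=data["R"],
                        )
                    )
            eigenblocks.append(eb)
        return cls(
            eigenblocks=eigenblocks,
            ld_blocks=ld_blocks or None,
            tol=manifest.get("tol", DEFAULT_EIGEN_TOL),
        )


def make_ld_reference(
    genotypes: np.ndarray,
    variant_ids: Sequence[str],
    block_assignments: Sequence[int],
    tol: float = DEFAULT_EIGEN_TOL,
    keep_r: bool = True,
) -> LDReference:
    """Build an eigen-decomposed LD reference from standardized genotypes.

    ``block_assignments`` maps each genotype column to a block id; every
    variant must belong to exactly one block and blocks must be contiguous
    runs of columns (genome order).
    """
    X = np.asarray(genotypes, dtype=float)
    if len(variant_ids) != X.shape[1] or len(block_assignments) != X.shape[1]:
        raise ValueError("variant_ids / block_assignments must match columns")
    if len(set(variant_ids)) != len(variant_ids):
        raise ValueError("duplicate variant id in LD reference input")
    assignments = np.asarray(block_assignments)
    if assignments.size == 0:
        raise ValueError("empty block assignment list")
    # contiguity check: each block id appears as one run
    change = np.flatnonzero(np.diff(assignments) != 0)
    run_ids = assignments[np.r_[0, change + 1]]
    if len(set(run_ids.tolist())) != len(run_ids):
        raise ValueError("a variant is assigned to two non-contiguous blocks")
    eigenblocks, ld_blocks = [], []
    for bid in run_ids:
        cols = np.flatnonzero(assignments == bid)
        blk = compute_block_ld(
            X[:, cols], [variant_ids[j] for j in cols], block_id=int(bid)
        )
        ld_blocks.append(blk)
        eigenblocks.append(eigendecompose(blk, tol=tol))
    return LDReference(
        eigenblocks=eigenblocks, ld_blocks=ld_blocks if keep_r else None, tol=tol
    )


def blocks_from_regions(
    chrom: Sequence[str],
    pos: Sequence[int],
    regions: Sequence[tuple[str, int, int]],
) -> np.ndarray:
    """Assign variants to blocks from (chrom, start, end) regions.

    Coordinates are 1-based inclusive.  Raises if a variant falls in two
    regions or in none.
    """
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    assignment = np.full(pos.shape[0], -1, dtype=int)
    for bid, (c, start, end) in enumerate(regions):
        inside = (chrom == c) & (pos >= start) & (pos <= end)
        clash = inside & (assignment >= 0)
        if np.any(clash):
            j = int(np.flatnonzero(clash)[0])
            raise ValueError(
                f"variant at {chrom[j]}:{pos[j]} falls in two block regions"
            )
        assignment[inside] = bid
    if np.any(assignment < 0):
        j = int(np.flatnonzero(assignment < 0)[0])
        raise ValueError(f"variant at {chrom[j]}:{pos[j]} not covered by any block")
    return assignment


def chunk_variants(n_variants: int, n_blocks: int) -> np.ndarray:
    """Fixed-count contiguous block assignment for synthetic data."""
    if n_blocks < 1 or n_variants < n_blocks:
        raise ValueError("need 1 <= n_blocks <= n_variants")
    return np.repeat(
        np.arange(n_blocks), np.diff(np.linspace(0, n_variants, n_blocks + 1).astype(int))
    )
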