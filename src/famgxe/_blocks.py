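"""Family-block data layout and batched Gaussian log-likelihood.

The variance-components likelihood factorizes over families.  Families are
grouped by size so each group's covariance blocks form a (n_fam, s, s)
array and the Cholesky factorizations are batched through numpy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class SizeGroup:
    """All families of one common size, stacked."""

    size: int
    families: list[str]
    K: np.ndarray  # (n_fam, s, s) additive relationship blocks (2*phi)
    y: np.ndarray  # (n_fam, s) trait scores
    q: np.ndarray | None  # (n_fam, s) standardized TDEE
    D: np.ndarray | None  # (n_fam, s, s) pairwise |q_i - q_j|


@dataclass
class BlockData:
    groups: list[SizeGroup]
    n: int  # total individuals
    ids: list[str]

    @property
    def n_families(self) -> int:
        return sum(len(g.families) for g in self.groups)


def build_blocks(ids, y, rel, q=None) -> BlockData:
    """Group aligned (ids, y, q) vectors into per-family-size stacked blocks.

    ``rel`` is a RelationshipMatrix covering at least ``ids``; individuals
    are grouped by their family and the corresponding 2*phi sub-blocks are
    extracted.  Raises if an id is missing from the relationship matrix.
    """
    ids = list(ids)
    y = np.asarray(y, dtype=float)
    q = None if q is None else np.asarray(q, dtype=float)
    missing = [i for i in ids if i not in rel.family_of]
    if missing:
        raise ValueError(
            f"ids not present in relationship matrix: {missing[:5]}"
        )
    fam_members: dict[str, list[int]] = {}
    for k, i in enumerate(ids):
        fam_members.setdefault(rel.family_of[i], []).append(k)

    by_size: dict[int, list[tuple[str, list[int]]]] = {}
    for fam, idx in fam_members.items():
        by_size.setdefault(len(idx), []).append((fam, idx))

    sub = rel.subset(ids)
    groups = []
    for size in sorted(by_size):
        entries = by_size[size]
        K = np.stack(
            [sub.values[np.ix_(idx, idx)] for _, idx in entries]
        )
        Y = np.stack([y[idx] for _, idx in entries])
        if q is not None:
            Q = np.stack([q[idx] for _, idx in entries])
            D = np.abs(Q[:, :, None] - Q[:, None, :])
        else:
            Q = D = None
        groups.append(
            SizeGroup(
                size=size,
                families=[fam for fam, _ in entries],
                K=K,
                y=Y,
                q=Q,
                D=D,
            )
        )
    return BlockData(groups=groups, n=len(ids), ids=ids)


def gaussian_loglik(blocks: BlockData, mu: float, omega_fn) -> float:
    """Sum of per-family Gaussian log-densities with mean mu.

    ``omega_fn(group) -> (n_fam, s, s)`` covariance blocks.  Returns -inf
    when any block fails its Cholesky factorization (invalid parameters).
    """
    total = -0.5 * blocks.n * _LOG_2PI
    for g in blocks.groups:
        omega = omega_fn(g)
        if not np.all(np.isfinite(omega)):
            return -np.inf
        try:
            chol = np.linalg.cholesky(omega)
        except np.linalg.LinAlgError:
            return -np.inf
        resid = g.y - mu
        u = np.linalg.solve(chol, resid[..., None])[..., 0]
        logdet = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=-2, axis2=-1)))
        total += -0.5 * (logdet + float(np.sum(u * u)))
    return float(total)
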