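"""Independent test oracles, deliberately naive implementations.

These re-derive quantities the package computes, through different
algorithms: exact enumeration of inheritance vectors for expected allele
sharing, and a dense multivariate-normal density for the family-block
likelihood.  They share no code with the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from famgxe.pedigree import Pedigree


def _topo_order(ped: Pedigree, members: list[str]) -> list[str]:
    order, placed = [], set()
    pending = list(members)
    while pending:
        progressed = False
        for iid in list(pending):
            ind = ped[iid]
            ok = all(
                p is None or p in placed or p not in members
                for p in (ind.father_id, ind.mother_id)
            )
            if ok:
                order.append(iid)
                placed.add(iid)
                pending.remove(iid)
                progressed = True
        if not progressed:
            raise ValueError("cycle in pedigree")
    return order


def exact_kinship2(ped: Pedigree) -> tuple[list[str], np.ndarray]:
    """Exact expected allele sharing by enumerating all inheritance vectors.

    Every transmission from a known parent is one binary choice; all 2^k
    joint choices are enumerated and allele identity is averaged exactly.
    Only feasible for small families (k <= ~16 transmissions).
    """
    ids = ped.ids
    index = {i: k for k, i in enumerate(ids)}
    out = np.zeros((len(ids), len(ids)))
    for fam, members in ped.families.items():
        order = _topo_order(ped, members)
        k_bits = sum(
            (ped[i].father_id is not None) + (ped[i].mother_id is not None)
            for i in order
        )
        if k_bits > 16:
            raise ValueError("family too large for exact enumeration")
        V = 1 << k_bits
        vec = np.arange(V)
        bit = 0
        alleles: dict[str, list[np.ndarray]] = {}
        label = 0
        for iid in order:
            ind = ped[iid]
            pair = []
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    pair.append(np.full(V, label))
                    label += 1
                else:
                    b = (vec >> bit) & 1
                    bit += 1
                    pa = alleles[pid]
                    pair.append(np.where(b == 1, pa[1], pa[0]))
            alleles[iid] = pair
        for a_pos, i in enumerate(order):
            gi = index[i]
            ai = alleles[i]
            out[gi, gi] = 1.0 + float(np.mean(ai[0] == ai[1]))
            for j in order[a_pos + 1:]:
                gj = index[j]
                aj = alleles[j]
                m = sum(
                    np.mean(ai[s] == aj[t]) for s in (0, 1) for t in (0, 1)
                )
                out[gi, gj] = out[gj, gi] = 2.0 * float(m) / 4.0
    return ids, out


def dense_mvn_loglik(y, mu, omega) -> float:
    """Log-density of y ~ N(mu*1, omega) via scipy's dense MVN."""
    y = np.asarray(y, dtype=float)
    return float(
        stats.multivariate_normal.logpdf(y, mean=np.full(y.size, mu), cov=omega)
    )


def random_pedigree(rng: np.random.Generator, n_extra: int = 6) -> Pedigree:
    """Random valid single-family pedigree with 4 founders + n_extra non-founders.

    Matings are sampled among existing members (including across
    generations), so inbreeding loops arise naturally.
    """
    from famgxe.pedigree import Individual

    inds = [
        Individual("f1", "FAM", None, None, "male"),
        Individual("f2", "FAM", None, None, "female"),
        Individual("f3", "FAM", None, None, "male"),
        Individual("f4", "FAM", None, None, "female"),
    ]
    males = ["f1", "f3"]
    females = ["f2", "f4"]
    for k in range(n_extra):
        fa = males[rng.integers(len(males))]
        mo = females[rng.integers(len(females))]
        sex = "male" if rng.random() < 0.5 else "female"
        iid = f"n{k}"
        inds.append(Individual(iid, "FAM", fa, mo, sex))
        (males if sex == "male" else females).append(iid)
    return Pedigree(inds)
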