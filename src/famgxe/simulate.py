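"""Synthetic nuclear-family study generator and gene-dropping oracle.

Emulates a family study of 294 nuclear families with roughly 958 phenotyped
members (180 fathers, 253 mothers, 265 sons, 260 daughters): complete
two-parent pedigrees carry the relationship structure, while participation
quotas decide who is phenotyped.  Role-conditional TDEE draws, optional
count-consistent 3-day activity diaries, and trait values drawn from the
same GxEE covariance code path the inference side uses.  Also provides a
Monte-Carlo gene-dropping estimator of expected allele sharing as an
independent check on the analytic kinship recursion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from famgxe.activity import (
    N_DAYS,
    N_PERIODS_PER_DAY,
    DiaryRecord,
    EnergyCostTable,
    write_diaries,
)
from famgxe.gxee import GxEEParams, _gxee_omega
from famgxe._blocks import build_blocks
from famgxe.pedigree import (
    Individual,
    Pedigree,
    RelationshipMatrix,
    kinship2,
    write_pedigree,
)

ROLES = ("father", "mother", "son", "daughter")

#: Role-conditional TDEE mean and SD in kcal/day (study descriptives).
DEFAULT_TDEE_MOMENTS = {
    "father": (3561.79, 962.71),
    "mother": (2788.37, 527.58),
    "son": (2280.57, 774.43),
    "daughter": (2024.85, 568.43),
}

#: Role-conditional age mean and SD in years (offspring are drawn uniform
#: on [10, 18] instead; see simulate_ages).
DEFAULT_AGE_MOMENTS = {"father": (45.36, 5.17), "mother": (43.49, 4.47)}

#: Role-conditional body weight (kg) mean and SD; needed only for diary
#: round-trips, chosen as typical adult/adolescent values.
DEFAULT_WEIGHT_MOMENTS = {
    "father": (78.0, 10.0),
    "mother": (65.0, 9.0),
    "son": (55.0, 12.0),
    "daughter": (50.0, 10.0),
}

#: Trait heritabilities used by the polygenic generator defaults.
DEFAULT_TRAIT_H2 = {
    "WC": 0.34, "SBP": 0.40, "GLU": 0.29,
    "HDL": 0.59, "TC": 0.51, "TG": 0.21,
}

#: Modest age/sex mean effects added to simulated traits (score scale) so
#: covariate adjustment has real work to do.
DEFAULT_COVARIATE_EFFECTS = {
    "intercept": 0.0, "sex": -0.3, "age": 0.04,
    "age2": -0.0005, "age_sex": -0.01, "age2_sex": 0.0002,
}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic family study.

    Defaults reproduce the reference design: 294 nuclear families with exact
    phenotyped role counts (180 fathers, 253 mothers, 265 sons, 260
    daughters; 958 subjects, mean family size 3.3).  Set ``role_counts`` to
    None to instead thin roles independently with ``participation``
    probabilities and draw family sizes from ``offspring_distribution``.
    """

    n_families: int = 294
    role_counts: tuple[int, int, int, int] | None = (180, 253, 265, 260)
    offspring_distribution: tuple[float, ...] = (0.5, 0.35, 0.12, 0.03)
    participation: dict = field(
        default_factory=lambda: {"father": 0.61, "mother": 0.86}
    )
    max_offspring: int = 4
    tdee_moments: dict = field(default_factory=lambda: dict(DEFAULT_TDEE_MOMENTS))
    tdee_truncation: float = 500.0  # kcal/day lower bound for draws
    age_moments: dict = field(default_factory=lambda: dict(DEFAULT_AGE_MOMENTS))
    offspring_age_range: tuple[float, float] = (10.0, 18.0)
    weight_moments: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHT_MOMENTS))
    trait_model: str = "polygenic"  # 'polygenic' | 'gxee'
    trait_h2: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_H2))
    total_variance: float = 1.0
    gxee_params: GxEEParams | None = None
    covariate_effects: dict | None = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    emit_diaries: bool = False
    seed: int = 0


@dataclass
class SyntheticStudy:
    """Fixture bundle: pedigree, phenotypes and the generating truth."""

    pedigree: Pedigree
    phenotypes: pd.DataFrame
    truth: dict
    diaries: list[DiaryRecord] = field(default_factory=list)

    @property
    def phenotyped_ids(self) -> list[str]:
        return [str(i) for i in self.phenotypes["individual_id"]]

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Emit the pedigree/phenotype/diary/truth files the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pedigree": str(outdir / "pedigree.ped"),
            "phenotypes": str(outdir / "phenotypes.csv"),
            "truth": str(outdir / "truth.json"),
        }
        write_pedigree(self.pedigree, paths["pedigree"])
        self.phenotypes.to_csv(paths["phenotypes"], index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
        if self.diaries:
            paths["diaries"] = str(outdir / "diaries.csv")
            write_diaries(self.diaries, paths["diaries"])
        return paths


def scale_role_counts(
    n_families: int,
    base_counts: tuple[int, int, int, int] = (180, 253, 265, 260),
    base_families: int = 294,
) -> tuple[int, int, int, int]:
    """Scale the reference phenotyped-role profile to another family count."""
    scaled = [max(1, round(c * n_families / base_families)) for c in base_counts]
    return tuple(scaled)


def _role_of(ped: Pedigree, iid: str) -> str:
    ind = ped[iid]
    if ind.is_founder:
        return "father" if ind.sex == "male" else "mother"
    return "son" if ind.sex == "male" else "daughter"


def simulate_pedigrees(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[Pedigree, list[str]]:
    """Generate complete nuclear-family pedigrees and the phenotyped subset.

    Both parents always appear in the pedigree (they carry the sibling
    relationship structure); participation thinning selects which parents
    are phenotyped.  All offspring are phenotyped (recruitment is through
    the children).  With ``role_counts`` set, phenotyped role totals match
    the configured profile exactly and every family keeps at least two
    phenotyped members.
    """
    rng = rng or np.random.default_rng(config.seed)
    nf = config.n_families

    if config.role_counts is not None:
        n_fa, n_mo, n_son, n_dau = config.role_counts
        n_children = n_son + n_dau
        if n_children < nf:
            raise ValueError("need at least one offspring per family")
        if n_children > nf * config.max_offspring:
            raise ValueError(
                f"{n_children} offspring cannot fit in {nf} families "
                f"of at most {config.max_offspring} children"
            )
        kids = np.ones(nf, dtype=int)
        extra = n_children - nf
        while extra > 0:
            open_f = np.flatnonzero(kids < config.max_offspring)
            take = min(extra, open_f.size)
            chosen = rng.choice(open_f, size=take, replace=False)
            kids[chosen] += 1
            extra -= take
        sex_pool = np.array([0] * n_son + [1] * n_dau)
        rng.shuffle(sex_pool)
        fa_part = np.zeros(nf, dtype=bool)
        fa_part[rng.choice(nf, size=n_fa, replace=False)] = True
        mo_part = np.zeros(nf, dtype=bool)
        mo_part[rng.choice(nf, size=n_mo, replace=False)] = True
        # repair: a 1-child family with neither parent phenotyped has < 2
        # phenotyped members; hand it participation from a well-covered family
        phen_n = kids + fa_part + mo_part
        for f in np.flatnonzero(phen_n < 2):
            for donor in np.argsort(-phen_n):
                if phen_n[donor] >= 3:
                    if fa_part[donor] and not fa_part[f]:
                        fa_part[donor], fa_part[f] = False, True
                    elif mo_part[donor] and not mo_part[f]:
                        mo_part[donor], mo_part[f] = False, True
                    else:
                        continue
                    phen_n = kids + fa_part + mo_part
                    break
    else:
        probs = np.asarray(config.offspring_distribution, dtype=float)
        kids = rng.choice(np.arange(1, probs.size + 1), size=nf, p=probs)
        sex_pool = rng.integers(0, 2, size=int(kids.sum()))
        fa_part = rng.random(nf) < config.participation.get("father", 1.0)
        mo_part = rng.random(nf) < config.participation.get("mother", 1.0)

    individuals: list[Individual] = []
    phenotyped: list[str] = []
    s = 0
    for f in range(nf):
        fam = f"F{f + 1:04d}"
        fa_id, mo_id = f"{fam}_F", f"{fam}_M"
        individuals.append(Individual(fa_id, fam, None, None, "male"))
        individuals.append(Individual(mo_id, fam, None, None, "female"))
        if fa_part[f]:
            phenotyped.append(fa_id)
        if mo_part[f]:
            phenotyped.append(mo_id)
        for c in range(int(kids[f])):
            cid = f"{fam}_C{c + 1}"
            sex = "male" if sex_pool[s] == 0 else "female"
            s += 1
            individuals.append(Individual(cid, fam, fa_id, mo_id, sex))
            phenotyped.append(cid)
    return Pedigree(individuals), phenotyped


def _truncated_normal(rng, mean, sd, lower, size=None) -> np.ndarray | float:
    scalar = size is None
    out = np.atleast_1d(rng.normal(mean, sd, size=size))
    bad = out < lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < lower
    return float(out[0]) if scalar else out


def _diary_from_tdee(
    iid: str, tdee: float, weight: float, costs: EnergyCostTable
) -> DiaryRecord:
    """Build a 3-day diary whose category counts reproduce ``tdee``.

    Greedy integer construction: all 288 periods start at category 1, then
    periods are upgraded to higher categories largest-delta first until the
    per-kg 3-day energy target is met; the rounding residual is below one
    15-min period's smallest cost increment.
    """
    c = costs.as_array()
    n_total = N_DAYS * N_PERIODS_PER_DAY
    target = N_DAYS * tdee / weight  # kcal/kg over 3 days
    if not (n_total * c[0] <= target <= n_total * c[-1]):
        raise ValueError(
            f"TDEE {tdee:.0f} kcal/day infeasible for weight {weight:.0f} kg"
        )
    counts = np.zeros(9, dtype=int)
    counts[0] = n_total
    remaining = target - n_total * c[0]
    for cat in range(8, 0, -1):
        delta = c[cat] - c[0]
        n_up = min(int(remaining / delta), int(counts[0]))
        if n_up > 0:
            counts[cat] += n_up
            counts[0] -= n_up
            remaining -= n_up * delta
    codes = np.repeat(np.arange(1, 10), counts)
    days = tuple(
        tuple(int(v) for v in codes[d * N_PERIODS_PER_DAY:(d + 1) * N_PERIODS_PER_DAY])
        for d in range(N_DAYS)
    )
    return DiaryRecord(individual_id=iid, days=days)


def simulate_tdee(
    ped: Pedigree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    ids=None,
    weights=None,
    costs: EnergyCostTable | None = None,
) -> tuple[pd.Series, list[DiaryRecord]]:
    """Role-conditional truncated-normal TDEE draws, optionally with diaries.

    Draws are normal per role, truncated below at ``config.tdee_truncation``
    kcal/day.  When ``config.emit_diaries`` is on, each individual also gets
    a 3-day diary whose category counts reproduce the drawn TDEE for the
    given body weight (infeasible draws are resampled).
    """
    rng = rng or np.random.default_rng(config.seed)
    ids = list(ids) if ids is not None else ped.ids
    costs = costs or EnergyCostTable()
    tdee = np.empty(len(ids))
    for k, iid in enumerate(ids):
        mean, sd = config.tdee_moments[_role_of(ped, iid)]
        tdee[k] = _truncated_normal(rng, mean, sd, config.tdee_truncation, None)
    series = pd.Series(tdee, index=ids, name="tdee")
    diaries: list[DiaryRecord] = []
    if config.emit_diaries:
        if weights is None:
            raise ValueError("diary emission requires body weights")
        c = costs.as_array()
        for iid in ids:
            w = float(weights[iid])
            lo = N_DAYS * N_PERIODS_PER_DAY * c[0] * w / N_DAYS
            hi = N_DAYS * N_PERIODS_PER_DAY * c[-1] * w / N_DAYS
            mean, sd = config.tdee_moments[_role_of(ped, iid)]
            while not (lo <= series[iid] <= hi):
                series[iid] = _truncated_normal(
                    rng, mean, sd, config.tdee_truncation, None
                )
            diaries.append(_diary_from_tdee(iid, float(series[iid]), w, costs))
    return series, diaries


def _draw_scores(ids, q, rel, params: GxEEParams, rng) -> pd.Series:
    """Draw per-family multivariate-normal scores under the GxEE covariance.

    Uses the same block-assembly code path as the likelihood, so the
    generator is the exact generative twin of the fitted model.
    """
    blocks = build_blocks(ids, np.zeros(len(ids)), rel, q=q)
    omega_fn = _gxee_omega(params)
    out = {}
    for g in blocks.groups:
        omega = omega_fn(g)
        if not np.all(np.isfinite(omega)):
            raise ValueError("non-finite generating covariance; check truth params")
        chol = np.linalg.cholesky(omega)
        z = rng.standard_normal((len(g.families), g.size))
        draws = params.mu + np.einsum("fij,fj->fi", chol, z)
        # recover which ids belong to each stacked family, in block order
        fam_members: dict[str, list[str]] = {}
        for i in ids:
            fam_members.setdefault(rel.family_of[i], []).append(i)
        for fam, row in zip(g.families, draws):
            for iid, val in zip(fam_members[fam], row):
                out[iid] = float(val)
    return pd.Series([out[i] for i in ids], index=ids)


def polygenic_truth(h2: float, total_variance: float = 1.0) -> GxEEParams:
    """GxEE parameterization of a pure polygenic truth (no interaction)."""
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must be in [0, 1)")
    sg2 = max(h2 * total_variance, 1e-12)
    se2 = (1.0 - h2) * total_variance
    return GxEEParams(
        alpha_g=float(np.log(sg2)), gamma_g=0.0, lam=0.0,
        alpha_e=float(np.log(se2)), gamma_e=0.0, mu=0.0,
    )


def simulate_traits(
    ped: Pedigree,
    tdee: pd.Series,
    truth: GxEEParams | dict[str, GxEEParams],
    rng: np.random.Generator | None = None,
    covariate_effects: dict | None = None,
    ages: pd.Series | None = None,
    sexes: pd.Series | None = None,
    rel: RelationshipMatrix | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw trait values for the individuals indexed by ``tdee``.

    TDEE is standardized within the sample and enters the generating
    covariance exactly as in the fitted model.  Optional age/sex mean
    effects are added on top of the family-structured scores.
    """
    rng = rng or np.random.default_rng(seed)
    ids = [str(i) for i in tdee.index]
    rel = rel or kinship2(ped)
    q = (tdee.to_numpy(dtype=float) - tdee.mean()) / tdee.std(ddof=1)
    truths = truth if isinstance(truth, dict) else {"trait": truth}
    df = pd.DataFrame({"individual_id": ids})
    for name, params in truths.items():
        y = _draw_scores(ids, q, rel, params, rng).to_numpy()
        if covariate_effects and ages is not None and sexes is not None:
            a = ages.loc[ids].to_numpy(dtype=float)
            s = sexes.loc[ids].map({"male": 0.0, "female": 1.0}).to_numpy(dtype=float)
            e = covariate_effects
            y = y + (
                e.get("intercept", 0.0)
                + e.get("sex", 0.0) * s
                + e.get("age", 0.0) * a
                + e.get("age2", 0.0) * a**2
                + e.get("age_sex", 0.0) * a * s
                + e.get("age2_sex", 0.0) * a**2 * s
            )
        df[name] = y
    return df


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a full fixture bundle under the configured truth.

    Pure function of the config (all randomness flows from ``config.seed``):
    identical configs produce identical studies.
    """
    rng = np.random.default_rng(config.seed)
    ped, phenotyped = simulate_pedigrees(config, rng)

    ages, sexes, weights = {}, {}, {}
    for iid in phenotyped:
        role = _role_of(ped, iid)
        sexes[iid] = ped[iid].sex
        if role in ("father", "mother"):
            m, s = config.age_moments[role]
            ages[iid] = float(rng.normal(m, s))
        else:
            lo, hi = config.offspring_age_range
            ages[iid] = float(rng.uniform(lo, hi))
        mw, sw = config.weight_moments[role]
        weights[iid] = float(max(rng.normal(mw, sw), 25.0))
    ages = pd.Series(ages)
    sexes = pd.Series(sexes)
    weights = pd.Series(weights)

    tdee, diaries = simulate_tdee(
        ped, config, rng, ids=phenotyped, weights=weights
    )

    if config.trait_model == "gxee":
        if config.gxee_params is None:
            raise ValueError("trait_model 'gxee' requires gxee_params")
        truths = {name: config.gxee_params for name in config.trait_h2}
    elif config.trait_model == "polygenic":
        truths = {
            name: polygenic_truth(h2, config.total_variance)
            for name, h2 in config.trait_h2.items()
        }
    else:
        raise ValueError(f"unknown trait_model {config.trait_model!r}")

    traits = simulate_traits(
        ped, tdee, truths, rng,
        covariate_effects=config.covariate_effects,
        ages=ages, sexes=sexes,
    )
    phen = pd.DataFrame({
        "individual_id": phenotyped,
        "family_id": [ped[i].family_id for i in phenotyped],
        "sex": [sexes[i] for i in phenotyped],
        "age": [round(ages[i], 2) for i in phenotyped],
        "weight": [round(weights[i], 1) for i in phenotyped],
        "tdee": [round(float(tdee[i]), 2) for i in phenotyped],
    })
    phen = phen.merge(traits, on="individual_id")
    truth_record = {
        "trait_model": config.trait_model,
        "n_individuals": len(ped),
        "n_phenotyped": len(phenotyped),
        "n_families": config.n_families,
        "seed": config.seed,
        "params": {
            name: {k: float(v) for k, v in asdict(p).items()}
            for name, p in truths.items()
        },
    }
    return SyntheticStudy(
        pedigree=ped, phenotypes=phen, truth=truth_record, diaries=diaries
    )


def gene_drop_kinship(
    ped: Pedigree, n_drops: int = 10_000, seed: int = 0
) -> tuple[RelationshipMatrix, np.ndarray]:
    """Monte-Carlo gene-dropping estimate of the relationship matrix.

    Each founder receives two unique allele labels; alleles are transmitted
    down the pedigree by Mendelian sampling.  The estimated 2*phi between i
    and j is twice the average of the four allele-matching indicators
    (diagonal: 1 plus the self allele-identity rate).  Returns the estimate
    and a matching matrix of Monte-Carlo standard errors (SE ~ 1/sqrt(n)).
    """
    if n_drops < 1:
        raise ValueError("n_drops must be >= 1")
    rng = np.random.default_rng(seed)
    ids = ped.ids
    index = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    est = np.zeros((n, n))
    se = np.zeros((n, n))
    for fam, members in ped.families.items():
        order = ped._topological_order(fam)
        m = len(order)
        pos = {i: k for k, i in enumerate(order)}
        alleles = np.empty((n_drops, m, 2), dtype=np.int64)
        next_label = 0
        for k, iid in enumerate(order):
            ind = ped[iid]
            for side, pid in ((0, ind.father_id), (1, ind.mother_id)):
                if pid is None:
                    alleles[:, k, side] = next_label
                    next_label += 1
                else:
                    pick = rng.integers(0, 2, size=n_drops)
                    alleles[:, k, side] = alleles[
                        np.arange(n_drops), pos[pid], pick
                    ]
        for a in range(m):
            ga = index[order[a]]
            f_rate = (alleles[:, a, 0] == alleles[:, a, 1]).astype(float)
            est[ga, ga] = 1.0 + f_rate.mean()
            se[ga, ga] = f_rate.std(ddof=1) / np.sqrt(n_drops) if n_drops > 1 else np.inf
            for b in range(a + 1, m):
                gb = index[order[b]]
                match = (
                    alleles[:, a, :, None] == alleles[:, b, None, :]
                ).sum(axis=(1, 2)).astype(float) / 2.0
                est[ga, gb] = est[gb, ga] = match.mean()
                s = match.std(ddof=1) / np.sqrt(n_drops) if n_drops > 1 else np.inf
                se[ga, gb] = se[gb, ga] = s
    family_of = {ind.individual_id: ind.family_id for ind in ped.individuals}
    return RelationshipMatrix(ids=ids, values=est, family_of=family_of), se
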