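"""Synthetic mother-neonate cohort generator.

Emulates the statistical structure the downstream analyses assume, so
every stage is testable without controlled-access clinical data:

* ~164 dyads described by ~200 mixed-type maternal variables organized
  in correlated blocks. Each block is generated from a latent Gaussian
  copula (one shared latent factor per block with loading sqrt(rho), so
  every within-block pair has correlation rho), then marginals are
  thresholded to binary (median cut), binned to ordinal (3-5 uniform
  quantile levels), or kept interval. Missingness is injected completely
  at random.
* Per-site, per-day compositional count tables drawn from a Dirichlet
  around a site-specific base composition with one dominant taxon per
  site (Streptococcus-dominant buccal, E. coli-dominant stool style),
  with multinomial counts at a uniform random sequencing depth. Planted
  effects shift designated taxa (composition) or flatten/sharpen the
  Dirichlet base (alpha diversity) for dyads in the high-scoring half of
  a source block.
* Binary preterm and NICU outcomes from logistic models on designated
  block scores; NICU additionally loads on the preterm indicator, since
  prematurity is the dominant clinical driver of NICU admission.

Everything is bit-reproducible under a fixed spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .factors import FactorTable
from .tables import CountTable, PRENATAL

__all__ = [
    "BlockSpec",
    "EffectSpec",
    "SyntheticCohortSpec",
    "generate_factor_table",
    "generate_microbiota",
    "generate_outcomes",
    "paper_like_spec",
    "null_spec",
    "write_cohort",
]

EFFECT_TARGETS = ("alpha_diversity", "composition", "outcome", "outcome_preterm", "outcome_nicu")
NEONATAL_SITES = ("buccal", "rectal", "stool")
MATERNAL_SITES = ("buccal", "rectal", "vaginal")


@dataclass
class BlockSpec:
    """One correlated block of maternal variables.

    ``type_mix`` gives the (binary, ordinal, interval) proportions;
    ``correlation`` is the common within-block latent correlation, in
    [0, 1).
    """

    size: int
    type_mix: tuple = (1 / 3, 1 / 3, 1 / 3)
    correlation: float = 0.8

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("block size must be >= 1")
        if not (0.0 <= self.correlation < 1.0):
            raise ValueError("within-block correlation must be in [0, 1)")
        s = sum(self.type_mix)
        if s <= 0:
            raise ValueError("type_mix must have positive mass")
        self.type_mix = tuple(t / s for t in self.type_mix)


@dataclass
class EffectSpec:
    """Planted effect of a source block on a downstream target."""

    block: int
    target: str
    effect_size: float
    taxon_indices: tuple = (1, 2)  # composition targets (per site)

    def __post_init__(self):
        if self.target not in EFFECT_TARGETS:
            raise ValueError(f"unknown effect target {self.target!r}")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        self.taxon_indices = tuple(self.taxon_indices)


@dataclass
class SyntheticCohortSpec:
    """Full configuration of a synthetic mother-neonate cohort."""

    n_dyads: int = 164
    blocks: list = field(default_factory=list)
    n_sites: int = 3
    n_taxa_per_site: int = 60
    sequencing_depth_range: tuple = (5000, 20000)
    effects: list = field(default_factory=list)
    missingness_rate: float = 0.05
    dirichlet_concentration: float = 40.0
    preterm_prevalence: float = 0.17
    nicu_prevalence: float = 0.10
    nicu_preterm_coef: float = 2.5
    seed: int = 0

    def __post_init__(self):
        if self.n_dyads < 4:
            raise ValueError("n_dyads must be at least 4")
        if not (0.0 <= self.missingness_rate < 1.0):
            raise ValueError("missingness_rate must be in [0, 1)")
        lo, hi = self.sequencing_depth_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid sequencing_depth_range")
        if self.n_sites < 1 or self.n_sites > len(NEONATAL_SITES):
            raise ValueError(f"n_sites must be in [1, {len(NEONATAL_SITES)}]")
        self.blocks = [
            b if isinstance(b, BlockSpec) else BlockSpec(**b) for b in self.blocks
        ]
        self.effects = [
            e if isinstance(e, EffectSpec) else EffectSpec(**e) for e in self.effects
        ]
        for e in self.effects:
            if e.block >= len(self.blocks) or e.block < 0:
                raise ValueError(f"effect references unknown block {e.block}")

    @property
    def n_variables(self) -> int:
        return sum(b.size for b in self.blocks)

    def dyad_ids(self) -> list[str]:
        width = len(str(self.n_dyads))
        return [f"D{i + 1:0{width}d}" for i in range(self.n_dyads)]

    # -- config file I/O ---------------------------------------------------

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortSpec":
        raw = yaml.safe_load(Path(path).read_text())
        raw["blocks"] = [BlockSpec(**b) for b in raw.get("blocks", [])]
        raw["effects"] = [EffectSpec(**e) for e in raw.get("effects", [])]
        for key in ("sequencing_depth_range",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage_rng(spec: SyntheticCohortSpec, stage: str) -> np.random.Generator:
    import zlib

    return np.random.default_rng((int(spec.seed) ^ zlib.crc32(stage.encode())) % 2**31)


# -- Factor table ----------------------------------------------------------


def generate_factor_table(spec: SyntheticCohortSpec) -> FactorTable:
    """Draw the dyad x variable maternal factor table (see module docstring).

    The returned table carries the ground-truth block label per variable
    (``block_labels``) and the latent per-dyad block score
    (``block_scores``), which downstream planted effects key off.
    """
    if not spec.blocks:
        raise ValueError("spec declares no variable blocks")
    rng = _stage_rng(spec, "factors")
    n = spec.n_dyads
    dyads = spec.dyad_ids()
    data = {}
    types = {}
    labels = {}
    scores = {}
    for b_idx, block in enumerate(spec.blocks):
        latent = rng.standard_normal(n)
        scores[b_idx] = latent
        rho = block.correlation
        raw = np.sqrt(rho) * latent[:, None] + np.sqrt(1 - rho) * rng.standard_normal(
            (n, block.size)
        )
        n_bin = int(round(block.type_mix[0] * block.size))
        n_ord = int(round(block.type_mix[1] * block.size))
        n_bin = min(n_bin, block.size)
        n_ord = min(n_ord, block.size - n_bin)
        kinds = ["binary"] * n_bin + ["ordinal"] * n_ord
        kinds += ["interval"] * (block.size - len(kinds))
        for v_idx in range(block.size):
            name = f"B{b_idx:02d}_V{v_idx:02d}"
            col = raw[:, v_idx]
            kind = kinds[v_idx]
            if kind == "binary":
                values = (col > np.median(col)).astype(float)
            elif kind == "ordinal":
                n_levels = int(rng.integers(3, 6))
                qs = np.quantile(col, np.linspace(0, 1, n_levels + 1)[1:-1])
                values = np.searchsorted(qs, col, side="right").astype(float)
            else:
                values = col.astype(float)
            data[name] = values
            types[name] = kind
            labels[name] = b_idx
    df = pd.DataFrame(data, index=dyads)
    if spec.missingness_rate > 0:
        mask = rng.random(df.shape) < spec.missingness_rate
        df = df.mask(mask)
    return FactorTable(
        data=df,
        types=types,
        block_labels=pd.Series(labels, name="block"),
        block_scores=pd.DataFrame(scores, index=dyads),
    )


def _high_half(scores: pd.Series) -> pd.Series:
    return scores > scores.median()


# -- Microbiota ------------------------------------------------------------


def generate_microbiota(spec: SyntheticCohortSpec, factors: FactorTable) -> CountTable:
    """Per-site, per-day 16S-style count tables for the whole cohort.

    Neonatal samples exist for days 0-2 at each site (no day-0 stool,
    matching real neonatal sampling); maternal samples come from a
    single pregnancy visit. One dominant taxon anchors each site's base
    composition. Composition effects add a log-fold shift to designated
    taxa for dyads in the high half of the source block score; alpha
    effects temper the base composition (p -> p^(1/e^effect), flattening
    it when the effect is positive, hence raising Shannon diversity).
    """
    if factors.block_scores is None:
        raise ValueError("factor table lacks ground-truth block scores")
    for eff in spec.effects:
        if eff.block not in factors.block_scores.columns:
            raise ValueError(f"effect references unknown block {eff.block}")
    rng = _stage_rng(spec, "microbiota")
    n_taxa = spec.n_taxa_per_site
    sites = NEONATAL_SITES[: spec.n_sites]
    dyads = list(factors.data.index)
    lo, hi = spec.sequencing_depth_range

    comp_effects = [e for e in spec.effects if e.target == "composition"]
    alpha_effects = [e for e in spec.effects if e.target == "alpha_diversity"]

    base_logw = {}
    taxa_names = {}
    for s_idx, site in enumerate(sites):
        # geometric decay with a clear per-site dominant taxon
        ranks = np.arange(n_taxa)
        logw = 3.5 - 0.12 * ranks + 0.3 * rng.standard_normal(n_taxa)
        logw[0] += 2.0  # dominant taxon
        base_logw[site] = logw
        taxa_names[site] = [f"{site}_taxon_{i:03d}" for i in range(n_taxa)]

    columns = {}
    meta_rows = []
    for site in sites:
        logw = base_logw[site]
        for d_idx, dyad in enumerate(dyads):
            shift = logw.copy()
            temper = 0.0
            for eff in comp_effects:
                if _high_half(factors.block_scores[eff.block]).iloc[d_idx]:
                    for t in eff.taxon_indices:
                        shift[t % n_taxa] += eff.effect_size
            for eff in alpha_effects:
                if _high_half(factors.block_scores[eff.block]).iloc[d_idx]:
                    temper += eff.effect_size
            p = np.exp(shift)
            p /= p.sum()
            if temper != 0.0:
                p = p ** (1.0 / np.exp(temper))
                p /= p.sum()
            days = ["0", "1", "2"] if site != "stool" else ["1", "2"]
            for day in days:
                depth = int(rng.integers(lo, hi + 1))
                comp = rng.dirichlet(spec.dirichlet_concentration * p)
                counts = rng.multinomial(depth, comp)
                sid = f"{dyad}_N_{site}_d{day}"
                columns[sid] = counts
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "subject_id": dyad,
                        "role": "neonate",
                        "site": site,
                        "day": day,
                        "collection_time": float(int(day) * 24 + rng.uniform(0, 24)),
                    }
                )
            # maternal pregnancy-visit sample at the matched site
            m_site = MATERNAL_SITES[sites.index(site)]
            depth = int(rng.integers(lo, hi + 1))
            comp = rng.dirichlet(spec.dirichlet_concentration * np.exp(logw) / np.exp(logw).sum())
            counts = rng.multinomial(depth, comp)
            sid = f"{dyad}_M_{m_site}_prenatal"
            columns[sid] = counts
            meta_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": dyad,
                    "role": "mother",
                    "site": m_site,
                    "day": PRENATAL,
                    "collection_time": float(rng.uniform(200, 280)),
                }
            )
    # one shared taxon axis: block-diagonal site taxa
    all_taxa = [t for site in sites for t in taxa_names[site]]
    offsets = {site: sites.index(site) * n_taxa for site in sites}
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    mat = np.zeros((len(all_taxa), len(columns)), dtype=np.int64)
    for j, sid in enumerate(columns):
        site = meta.loc[sid, "site"]
        n_site = site if site in sites else sites[MATERNAL_SITES.index(site)]
        off = offsets[n_site]
        mat[off : off + n_taxa, j] = columns[sid]
    counts = pd.DataFrame(mat, index=all_taxa, columns=list(columns))
    return CountTable(counts, meta)


# -- Outcomes --------------------------------------------------------------


def generate_outcomes(spec: SyntheticCohortSpec, factors: FactorTable) -> pd.DataFrame:
    """Binary preterm and NICU outcomes from logistic models.

    Intercepts are set to logit(baseline prevalence); designated block
    scores (standardized latents) enter with the configured
    coefficients; the NICU linear predictor additionally includes
    ``nicu_preterm_coef`` times the preterm indicator.
    """
    if factors.block_scores is None:
        raise ValueError("factor table lacks ground-truth block scores")
    rng = _stage_rng(spec, "outcomes")
    n = len(factors.data.index)

    def logit(p):
        return np.log(p / (1 - p))

    lp_pre = np.full(n, logit(spec.preterm_prevalence))
    lp_nicu = np.full(n, logit(spec.nicu_prevalence))
    for eff in spec.effects:
        if eff.target not in ("outcome", "outcome_preterm", "outcome_nicu"):
            continue
        score = factors.block_scores[eff.block].to_numpy()
        score = (score - score.mean()) / max(score.std(), 1e-12)
        if eff.target == "outcome_preterm":
            lp_pre = lp_pre + eff.effect_size * score
        else:  # outcome / outcome_nicu
            lp_nicu = lp_nicu + eff.effect_size * score

    preterm = (rng.random(n) < 1 / (1 + np.exp(-lp_pre))).astype(int)
    if spec.nicu_preterm_coef:
        lp_nicu = lp_nicu + spec.nicu_preterm_coef * (preterm - preterm.mean())
    nicu = (rng.random(n) < 1 / (1 + np.exp(-lp_nicu))).astype(int)
    return pd.DataFrame(
        {"preterm": preterm, "nicu": nicu}, index=factors.data.index
    )


# -- Canned specs ----------------------------------------------------------


def paper_like_spec(seed: int = 0) -> SyntheticCohortSpec:
    """Cohort emulating the study conditions: 164 dyads, ~200 mixed-type
    variables in 13 correlated blocks plus an uncorrelated leftover
    block, 3 neonatal body sites, and planted diet/cytokine/preterm
    style effects on diversity, composition and outcomes."""
    sizes = [20, 18, 16, 15, 15, 14, 14, 12, 12, 12, 11, 10, 10]
    mixes = [
        (0.4, 0.4, 0.2), (0.2, 0.5, 0.3), (0.6, 0.2, 0.2), (0.3, 0.3, 0.4),
        (0.2, 0.2, 0.6), (0.1, 0.6, 0.3), (0.3, 0.5, 0.2), (0.0, 0.0, 1.0),
        (0.0, 0.0, 1.0), (0.0, 0.0, 1.0), (0.0, 0.0, 1.0), (0.5, 0.2, 0.3),
        (0.7, 0.1, 0.2),
    ]
    blocks = [BlockSpec(size=s, type_mix=m, correlation=0.8) for s, m in zip(sizes, mixes)]
    blocks.append(BlockSpec(size=21, type_mix=(0.4, 0.3, 0.3), correlation=0.0))
    effects = [
        EffectSpec(block=0, target="alpha_diversity", effect_size=1.0),
        EffectSpec(block=5, target="composition", effect_size=2.0),
        EffectSpec(block=11, target="outcome_preterm", effect_size=2.0),
        EffectSpec(block=10, target="outcome_nicu", effect_size=1.5),
    ]
    return SyntheticCohortSpec(
        n_dyads=164, blocks=blocks, effects=effects, seed=seed
    )


def null_spec(
    n_dyads: int = 164, n_variables: int = 200, seed: int = 0,
    missingness_rate: float = 0.0,
) -> SyntheticCohortSpec:
    """Fully null cohort: independent variables, no planted effects."""
    block = BlockSpec(size=n_variables, type_mix=(1 / 3, 1 / 3, 1 / 3), correlation=0.0)
    return SyntheticCohortSpec(
        n_dyads=n_dyads,
        blocks=[block],
        effects=[],
        missingness_rate=missingness_rate,
        seed=seed,
    )


def write_cohort(spec: SyntheticCohortSpec, outdir) -> dict:
    """Generate and write factor table, counts, outcomes and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    factors = generate_factor_table(spec)
    table = generate_microbiota(spec, factors)
    outcomes = generate_outcomes(spec, factors)
    paths = {
        "factors": outdir / "factors.tsv",
        "factor_types": outdir / "factor_types.tsv",
        "counts": outdir / "counts.tsv",
        "sample_meta": outdir / "sample_meta.tsv",
        "outcomes": outdir / "outcomes.tsv",
        "block_scores": outdir / "block_scores.tsv",
        "spec": outdir / "cohort_spec.yaml",
    }
    factors.to_tsv(paths["factors"], paths["factor_types"])
    from .tables import write_counts

    write_counts(table, paths["counts"], paths["sample_meta"])
    outcomes.to_csv(paths["outcomes"], sep="\t", index_label="dyad_id")
    factors.block_scores.to_csv(paths["block_scores"], sep="\t", index_label="dyad_id")
    spec.to_yaml(paths["spec"])
    return {k: str(v) for k, v in paths.items()}
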