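"""Synthetic structured panels, biparental crosses, and multi-environment trials.

The generator emulates the data an inbred small-grain breeding program would
feed into genomic selection: a diverse panel with subpopulation structure
(Balding-Nichols allele-frequency model), fully homozygous biparental progeny
(doubled haploids and recombinant inbred lines under a Haldane
no-interference crossover model), quantitative traits controlled by a
configurable number of QTL plus optional major covariate loci, and plot-level
phenotypes with environment main effects, genotype-by-environment
interaction, block effects and residual noise.

All operations are bit-reproducible given their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomat import GenotypeMatrix

__all__ = [
    "PanelSpec",
    "TraitArchitecture",
    "EnvDesign",
    "simulate_panel",
    "simulate_family_panel",
    "simulate_biparental",
    "simulate_phenotypes",
    "mask_genotypes",
]


@dataclass
class PanelSpec:
    """Parameters of a structured diversity panel of inbred lines.

    ``fst`` is the Balding-Nichols divergence of subpopulation allele
    frequencies from the ancestral pool; ``maf_range`` bounds the ancestral
    minor allele frequency.  Markers are spread over ``n_chroms`` chromosomes
    of ``map_length_per_chrom`` Morgans each.
    """

    n_lines: int = 239
    n_markers: int = 5600
    n_subpops: int = 3
    fst: float = 0.15
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_chroms: int = 21
    map_length_per_chrom: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_markers < self.n_chroms:
            raise ValueError("need at least one marker per chromosome")

    def subpop_sizes(self) -> list[int]:
        base, extra = divmod(self.n_lines, self.n_subpops)
        return [base + (1 if k < extra else 0) for k in range(self.n_subpops)]


@dataclass
class TraitArchitecture:
    """Additive genetic architecture of a simulated trait.

    ``qtl_effects`` are in trait units per allele dose on the -1/+1 coding.
    ``major_gene_indices`` mark loci that double as binary covariates
    (photoperiod / vernalization analogs); they stay ordinary markers in the
    genotype matrix so downstream stages may exclude them or promote them to
    fixed effects.  If ``target_h2`` is set, the residual standard deviation
    is derived so the entry-mean heritability
    ``h2 = s2_G / (s2_G + s2_GxE / e + s2_resid / (e r))`` hits the target;
    otherwise the literal standard deviations are used.
    """

    qtl_indices: list[int] = field(default_factory=list)
    qtl_effects: list[float] = field(default_factory=list)
    major_gene_indices: list[int] = field(default_factory=list)
    major_gene_effects: list[float] = field(default_factory=list)
    target_h2: float | None = None
    mu: float = 0.0
    env_main_sd: float = 1.0
    gxe_sd: float = 0.5
    block_sd: float = 0.1
    resid_sd: float = 1.0

    def __post_init__(self) -> None:
        if len(self.qtl_indices) != len(self.qtl_effects):
            raise ValueError("qtl_indices and qtl_effects lengths differ")
        if len(self.major_gene_indices) != len(self.major_gene_effects):
            raise ValueError("major gene index/effect lengths differ")
        if self.target_h2 is not None and not (0.0 < self.target_h2 <= 1.0):
            raise ValueError("target_h2 must be in (0, 1]")


@dataclass
class EnvDesign:
    """Multi-environment trial layout: environments x blocks(=replicates)."""

    n_envs: int = 8
    n_reps: int = 2
    env_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_envs < 1 or self.n_reps < 1:
            raise ValueError("all design counts must be >= 1")
        if self.env_labels is None:
            self.env_labels = [f"E{i + 1}" for i in range(self.n_envs)]
        elif len(self.env_labels) != self.n_envs:
            raise ValueError("env_labels length must equal n_envs")


def _make_map(spec_markers: int, n_chroms: int, length: float, rng: np.random.Generator) -> pd.DataFrame:
    chrom_of = np.sort(rng.integers(0, n_chroms, size=spec_markers))
    # guarantee every chromosome is hit
    for c in range(n_chroms):
        if not np.any(chrom_of == c):
            chrom_of[rng.integers(0, spec_markers)] = c
            chrom_of = np.sort(chrom_of)
    pos = np.empty(spec_markers)
    for c in range(n_chroms):
        idx = np.flatnonzero(chrom_of == c)
        pos[idx] = np.sort(rng.uniform(0.0, length * 100.0, size=idx.size))
    return pd.DataFrame(
        {
            "marker": [f"M{j + 1}" for j in range(spec_markers)],
            "chrom": [f"chr{c + 1}" for c in chrom_of],
            "position_cM": pos,
        }
    )


def simulate_panel(spec: PanelSpec) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate a structured panel of fully homozygous lines.

    Ancestral allele frequencies are uniform on ``maf_range``; each
    subpopulation draws its own frequency from the Balding-Nichols beta
    ``Beta(p (1-F)/F, (1-p)(1-F)/F)`` (``F = fst``; ``F = 0`` keeps the
    ancestral frequency exactly).  Each inbred line is homozygous ``+1`` at a
    marker with its subpopulation's frequency.  Markers that come out
    monomorphic across the panel are redrawn so every marker segregates.

    Returns the genotype matrix (codes strictly in ``{-1, +1}``, no missing)
    and the integer subpopulation label of each line.
    """
    rng = np.random.default_rng(spec.seed)
    p_anc = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=spec.n_markers)

    sizes = spec.subpop_sizes()
    labels = np.repeat(np.arange(spec.n_subpops), sizes)

    if spec.fst > 0.0:
        shape = (1.0 - spec.fst) / spec.fst
        p_sub = rng.beta(p_anc * shape, (1.0 - p_anc) * shape, size=(spec.n_subpops, spec.n_markers))
    else:
        p_sub = np.tile(p_anc, (spec.n_subpops, 1))

    values = np.where(
        rng.random((spec.n_lines, spec.n_markers)) < p_sub[labels], 1.0, -1.0
    )

    # redraw monomorphic columns so every marker has MAF > 0 in the panel
    for _ in range(20):
        mono = np.flatnonzero(np.ptp(values, axis=0) == 0)
        if mono.size == 0:
            break
        values[:, mono] = np.where(
            rng.random((spec.n_lines, mono.size)) < p_sub[labels][:, mono], 1.0, -1.0
        )
    mono = np.flatnonzero(np.ptp(values, axis=0) == 0)
    for j in mono:  # pathological frequencies: force one discordant line
        i = rng.integers(0, spec.n_lines)
        values[i, j] = -values[i, j]

    gmap = _make_map(spec.n_markers, spec.n_chroms, spec.map_length_per_chrom, rng)
    line_ids = [f"L{i + 1:04d}" for i in range(spec.n_lines)]
    g = GenotypeMatrix(values, line_ids, list(gmap["marker"]), gmap)
    return g, labels


def _gamete(
    p1: np.ndarray,
    p2: np.ndarray,
    chrom_codes: np.ndarray,
    pos_cm: np.ndarray,
    n_chroms: int,
    expansion: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete: Poisson crossover count, uniform positions."""
    out = np.empty_like(p1)
    for c in range(n_chroms):
        idx = np.flatnonzero(chrom_codes == c)
        pos = pos_cm[idx] / 100.0 * expansion  # Morgans on the (possibly expanded) map
        length = pos[-1] - pos[0] if idx.size > 1 else 0.0
        n_xo = rng.poisson(length)
        xo = np.sort(rng.uniform(pos[0], pos[0] + length, size=n_xo)) if n_xo else np.empty(0)
        phase = int(rng.integers(0, 2))
        segment = (np.searchsorted(xo, pos, side="right") + phase) % 2
        out[idx] = np.where(segment == 0, p1[idx], p2[idx])
    return out


def simulate_biparental(
    parent1: np.ndarray,
    parent2: np.ndarray,
    n_progeny: int,
    pop_type: str,
    genetic_map: pd.DataFrame,
    seed: int = 0,
    id_prefix: str = "P",
) -> GenotypeMatrix:
    """Simulate fully homozygous progeny of a biparental cross.

    ``pop_type`` is ``"DH"`` (doubled haploid: one meiosis, gamete doubled)
    or ``"RIL"`` (recombinant inbred line, approximated as a DH on a map
    expanded by a factor 2 to account for the extra effective recombination
    accumulated over selfing generations).  Crossovers follow the Haldane
    no-interference model: Poisson count per chromosome, uniform positions.
    """
    parent1 = np.asarray(parent1, float)
    parent2 = np.asarray(parent2, float)
    if parent1.shape != parent2.shape or parent1.shape[0] != len(genetic_map):
        raise ValueError("parents must share one marker set matching the map")
    for p in (parent1, parent2):
        if not np.all(np.isin(p, (-1.0, 1.0))):
            raise ValueError("parents must be fully homozygous (+1/-1) with no missing")
    if pop_type not in ("DH", "RIL"):
        raise ValueError("pop_type must be 'DH' or 'RIL'")
    expansion = 2.0 if pop_type == "RIL" else 1.0

    rng = np.random.default_rng(seed)
    chroms, chrom_codes = np.unique(genetic_map["chrom"].to_numpy(), return_inverse=True)
    pos = genetic_map["position_cM"].to_numpy(float)
    values = np.empty((n_progeny, parent1.size))
    for i in range(n_progeny):
        values[i] = _gamete(parent1, parent2, chrom_codes, pos, len(chroms), expansion, rng)
    ids = [f"{id_prefix}{i + 1:04d}" for i in range(n_progeny)]
    return GenotypeMatrix(values, ids, list(genetic_map["marker"].astype(str)), genetic_map)


def genetic_values(g: GenotypeMatrix, arch: TraitArchitecture) -> np.ndarray:
    """True additive genetic value of each line (QTL plus major-gene loci)."""
    gv = np.full(g.n_lines, arch.mu)
    for idx, eff in zip(arch.qtl_indices, arch.qtl_effects):
        gv += g.values[:, idx] * eff
    for idx, eff in zip(arch.major_gene_indices, arch.major_gene_effects):
        gv += g.values[:, idx] * eff
    return gv


def _noise_for_target(
    gvar: float, gxe_sd: float, target_h2: float, e: int, r: int
) -> tuple[float, float]:
    """(gxe_sd, resid_sd) hitting the target entry-mean heritability.

    The non-genetic entry-mean variance implied by the target is
    ``gvar (1/h2 - 1)``.  The configured G-by-E variance is kept if it fits
    inside that budget; otherwise it is shrunk to half the budget (it cannot
    simply be kept, e.g. for a narrow biparental cross whose genetic variance
    is far below the panel's) and the residual picks up the remainder.
    """
    nongenetic = gvar * (1.0 / target_h2 - 1.0)
    s2_gxe = gxe_sd**2
    if s2_gxe / e > nongenetic:
        s2_gxe = 0.5 * nongenetic * e
    s2_resid = (nongenetic - s2_gxe / e) * e * r
    return float(np.sqrt(s2_gxe)), float(np.sqrt(max(s2_resid, 0.0)))


def simulate_phenotypes(
    g: GenotypeMatrix,
    arch: TraitArchitecture,
    design: EnvDesign,
    seed: int = 0,
    trait: str = "trait",
) -> pd.DataFrame:
    """Simulate plot-level phenotypes for every line in every env x block.

    Plot value = mu + sum(dose x effect) + env main effect + GxE draw +
    block-within-env effect + residual.  Returns a long-format table with
    columns ``entry, env, block, rep, trait, value``.
    """
    rng = np.random.default_rng(seed)
    gv = genetic_values(g, arch)
    e, r = design.n_envs, design.n_reps
    gxe_sd, resid_sd = arch.gxe_sd, arch.resid_sd
    if arch.target_h2 is not None:
        gvar = float(np.var(gv, ddof=1))
        if gvar == 0.0:
            raise ValueError("target_h2 set but the trait has no genetic variance")
        gxe_sd, resid_sd = _noise_for_target(gvar, arch.gxe_sd, arch.target_h2, e, r)

    n = g.n_lines
    env_eff = rng.normal(0.0, arch.env_main_sd, size=e)
    gxe = rng.normal(0.0, gxe_sd, size=(n, e)) if gxe_sd > 0 else np.zeros((n, e))
    block_eff = rng.normal(0.0, arch.block_sd, size=(e, r)) if arch.block_sd > 0 else np.zeros((e, r))

    rows = []
    for j in range(e):
        for k in range(r):
            noise = rng.normal(0.0, resid_sd, size=n) if resid_sd > 0 else np.zeros(n)
            vals = gv + env_eff[j] + gxe[:, j] + block_eff[j, k] + noise
            rows.append(
                pd.DataFrame(
                    {
                        "entry": g.line_ids,
                        "env": design.env_labels[j],
                        "block": f"B{k + 1}",
                        "rep": k + 1,
                        "trait": trait,
                        "value": vals,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_family_panel(
    spec: PanelSpec,
    n_founders_per_subpop: int = 4,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate a structured panel with linkage disequilibrium.

    A pure Balding-Nichols panel draws every marker independently, so its
    only LD is global population structure; marker effects fitted on such a
    panel generalize solely through subpopulation alignment.  Breeding-
    program germplasm instead descends from a limited founder pool, which
    creates within-chromosome LD.  This generator emulates that: founders
    are drawn per subpopulation under the Balding-Nichols model (divergence
    ``fst``), and each panel line is a recombinant inbred from a random
    founder pair of its subpopulation, so lines are mosaics of founder
    haplotypes with realistic linkage blocks.

    Returns the panel and integer subpopulation labels.
    """
    founder_spec = PanelSpec(
        n_lines=n_founders_per_subpop * spec.n_subpops,
        n_markers=spec.n_markers,
        n_subpops=spec.n_subpops,
        fst=spec.fst,
        maf_range=spec.maf_range,
        n_chroms=spec.n_chroms,
        map_length_per_chrom=spec.map_length_per_chrom,
        seed=spec.seed,
    )
    founders, founder_labels = simulate_panel(founder_spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2**20]))
    gmap = founders.genetic_map
    chroms, chrom_codes = np.unique(gmap["chrom"].to_numpy(), return_inverse=True)
    pos = gmap["position_cM"].to_numpy(float)

    sizes = spec.subpop_sizes()
    labels = np.repeat(np.arange(spec.n_subpops), sizes)
    values = np.empty((spec.n_lines, spec.n_markers))
    for i, sub in enumerate(labels):
        pool = np.flatnonzero(founder_labels == sub)
        i1, i2 = rng.choice(pool, size=2, replace=False)
        values[i] = _gamete(
            founders.values[i1], founders.values[i2], chrom_codes, pos,
            len(chroms), 2.0, rng,  # RIL: doubled-map Haldane meiosis
        )
    # a marker fixed across all families is uninformative but legal; keep it
    line_ids = [f"L{i + 1:04d}" for i in range(spec.n_lines)]
    g = GenotypeMatrix(values, line_ids, list(founders.marker_ids), gmap)
    return g, labels


def sample_architecture(
    g: GenotypeMatrix,
    n_qtl: int,
    seed: int = 0,
    effect_sd: float = 1.0,
    n_major: int = 0,
    major_effect: float = 0.0,
    target_h2: float | None = None,
    mu: float = 0.0,
    env_main_sd: float = 1.0,
    gxe_sd: float = 0.5,
    block_sd: float = 0.1,
    resid_sd: float = 1.0,
) -> TraitArchitecture:
    """Draw a random trait architecture on an existing panel.

    QTL positions are sampled uniformly among segregating markers with
    effects ``N(0, effect_sd^2)``; major covariate loci (fixed effect size
    ``major_effect``) are drawn from intermediate-frequency markers so the
    binary covariate actually varies in subsamples.
    """
    rng = np.random.default_rng(seed)
    maf = g.maf()
    segregating = np.flatnonzero(maf > 0)
    if n_qtl + n_major > segregating.size:
        raise ValueError("not enough segregating markers for the requested architecture")
    common = np.flatnonzero(maf >= 0.2)
    major_pool = common if common.size >= n_major else segregating
    major = rng.choice(major_pool, size=n_major, replace=False) if n_major else np.empty(0, int)
    remaining = np.setdiff1d(segregating, major)
    qtl = rng.choice(remaining, size=n_qtl, replace=False)
    return TraitArchitecture(
        qtl_indices=[int(j) for j in qtl],
        qtl_effects=list(rng.normal(0.0, effect_sd, size=n_qtl)),
        major_gene_indices=[int(j) for j in major],
        major_gene_effects=[major_effect] * int(n_major),
        target_h2=target_h2,
        mu=mu,
        env_main_sd=env_main_sd,
        gxe_sd=gxe_sd,
        block_sd=block_sd,
        resid_sd=resid_sd,
    )


def mask_genotypes(
    g: GenotypeMatrix, missing_rate: float, seed: int = 0
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Set entries missing uniformly at random; returns (masked copy, mask).

    The mask (True = hidden) lets callers score imputation against the
    retained original values.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = rng.random(g.values.shape) < missing_rate
    values = g.values.copy()
    values[mask] = np.nan
    masked = GenotypeMatrix(values, list(g.line_ids), list(g.marker_ids), g.genetic_map)
    return masked, mask
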