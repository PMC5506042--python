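"""Synthetic inputs with the statistical structure the analysis assumes.

The simulator emulates a two-diet (regular chow vs high-fat diet),
three-age (weeks 1, 9, 18), three-replicate expression study:

* an *endogenous* rank-1 component whose sample loadings increase with age
  in every animal;
* an *exogenous* rank-1 component supported only on the HFD samples and
  constructed exactly orthogonal to the endogenous loading, so it vanishes
  from a control-only decomposition by design;
* i.i.d. Gaussian noise on the log2 scale.

`endo_strength`/`exo_strength` are per-gene RMS amplitudes: a planted
component contributes ``strength * sqrt(n_genes)`` to the singular
spectrum, so with the defaults (8 and 5 vs unit noise) both components sit
far above the random-matrix detection threshold, as a real, strongly
expressed tissue program would.

Also generated here: probe-level chip pairs with spatial artifacts for the
normalization stage, gene-set collections with one set planted at an
eigenvector extreme, and promoter sequences with motif occurrences
enriched among high-loading genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng

from .preprocess import ProbeChip
from .profiles import ExpressionProfile


@dataclass
class SimulationSpec:
    """Parameters of the synthetic expression study (defaults = study design)."""

    n_genes: int = 2000
    samples_per_cell: int = 3          # replicates per diet x week cell
    weeks: tuple = (1, 9, 18)
    endo_strength: float = 8.0         # per-gene RMS amplitude of the age component
    exo_strength: float = 5.0          # per-gene RMS amplitude of the diet component
    noise_sd: float = 1.0
    seed: int = 0
    planted_set_size: int = 50
    planted_set_end: str = "high"

    def validate(self) -> None:
        if self.n_genes <= 0 or self.samples_per_cell <= 0:
            raise ValueError("n_genes and samples_per_cell must be positive")
        if len(self.weeks) < 2:
            raise ValueError("need at least two distinct weeks")
        if len(set(self.weeks)) != len(self.weeks):
            raise ValueError("weeks must be distinct")
        if self.endo_strength < 0 or self.exo_strength < 0 or self.noise_sd < 0:
            raise ValueError("strengths and noise_sd must be nonnegative")
        if self.planted_set_size <= 0 or self.planted_set_size > self.n_genes:
            raise ValueError("planted_set_size must be in 1..n_genes")
        if self.planted_set_end not in ("low", "high"):
            raise ValueError("planted_set_end must be 'low' or 'high'")


@dataclass
class GroundTruth:
    """Planted structure recorded for downstream verification."""

    endo_u: np.ndarray
    endo_v: np.ndarray
    exo_u: np.ndarray
    exo_v: np.ndarray
    rho_endo: float
    rho_exo: float
    genes: list
    samples: list
    planted_sets: dict = field(default_factory=dict)   # name -> {"members": [...], "end": ...}
    planted_motif_genes: list = field(default_factory=list)


def _sample_table(spec: SimulationSpec) -> pd.DataFrame:
    rows = []
    counter = 1
    for diet in ("RC", "HFD"):
        letter = "R" if diet == "RC" else "H"
        for week in spec.weeks:
            for _ in range(spec.samples_per_cell):
                rows.append(
                    {"sample_id": f"{letter}{counter}L-W{week}", "diet": diet, "week": week}
                )
                counter += 1
    return pd.DataFrame(rows).set_index("sample_id")


def _planted_sample_loadings(attrs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Construct orthogonal endogenous and exogenous unit sample loadings.

    endo_v: centered week values (monotone in age).  exo_v: week-scaled HFD
    indicator, Gram-Schmidt against the endogenous loading restricted to
    the HFD support so the control entries remain exactly zero; both unit
    norm and exactly orthogonal.
    """
    weeks = attrs["week"].to_numpy(dtype=float)
    hfd = (attrs["diet"] == "HFD").to_numpy()
    endo = weeks - weeks.mean()
    endo_norm = np.linalg.norm(endo)
    if endo_norm < 1e-12:
        raise ValueError("degenerate sample layout: week has no variation")
    endo = endo / endo_norm

    raw = np.where(hfd, weeks, 0.0)
    endo_masked = np.where(hfd, endo, 0.0)
    denom = float(endo_masked @ endo_masked)
    if denom < 1e-12:
        raise ValueError("degenerate sample layout: no HFD variation along age")
    exo = raw - (raw @ endo) / denom * endo_masked
    exo_norm = np.linalg.norm(exo)
    if exo_norm < 1e-10 * max(1.0, np.linalg.norm(raw)):
        raise ValueError("non-orthogonalizable loading design (degenerate sample layout)")
    exo = exo / exo_norm
    # exact zero outside HFD support by construction
    exo[~hfd] = 0.0
    return endo, exo


def generate_profile(spec: SimulationSpec) -> tuple[ExpressionProfile, GroundTruth]:
    """Planted rank-2 log-expression matrix plus Gaussian noise.

    matrix = rho_endo * endo_u endo_v^T + rho_exo * exo_u exo_v^T + noise,
    with rho = strength * sqrt(n_genes) and unit u, v.
    """
    spec.validate()
    rng = default_rng(spec.seed)
    attrs = _sample_table(spec)
    endo_v, exo_v = _planted_sample_loadings(attrs)

    g = spec.n_genes
    # orthonormal random gene eigenvectors
    q, _ = np.linalg.qr(rng.standard_normal((g, 2)))
    endo_u, exo_u = q[:, 0], q[:, 1]

    rho_endo = spec.endo_strength * np.sqrt(g)
    rho_exo = spec.exo_strength * np.sqrt(g)
    m = rho_endo * np.outer(endo_u, endo_v) + rho_exo * np.outer(exo_u, exo_v)
    if spec.noise_sd > 0:
        m = m + spec.noise_sd * rng.standard_normal(m.shape)

    genes = [f"g{i:05d}" for i in range(g)]
    values = pd.DataFrame(m, index=pd.Index(genes, name="gene_id"), columns=attrs.index)

    # diabetic-phenotype attributes at the terminal week: HFD shifted upward
    attrs = attrs.copy()
    last_week = max(spec.weeks)
    terminal = attrs["week"] == last_week
    gtt = np.full(len(attrs), np.nan)
    itt = np.full(len(attrs), np.nan)
    hfd = (attrs["diet"] == "HFD").to_numpy()
    idx = np.where(terminal.to_numpy())[0]
    gtt[idx] = rng.normal(1000.0, 80.0, len(idx)) + 400.0 * hfd[idx]
    itt[idx] = rng.normal(500.0, 50.0, len(idx)) + 200.0 * hfd[idx]
    attrs["gtt_auc"] = gtt
    attrs["itt_auc"] = itt
    subgroup = pd.Series(pd.NA, index=attrs.index, dtype="object")
    hw18 = attrs.index[(attrs["diet"] == "HFD") & terminal]
    if len(hw18):
        med = attrs.loc[hw18, "gtt_auc"].median()
        subgroup[hw18] = np.where(attrs.loc[hw18, "gtt_auc"] > med, "Gw", "Gb")
    attrs["subgroup"] = subgroup

    # planted gene set at the designated extreme of the endogenous eigenvector
    order = np.argsort(endo_u)
    if spec.planted_set_end == "high":
        members = [genes[i] for i in order[-spec.planted_set_size:]]
    else:
        members = [genes[i] for i in order[: spec.planted_set_size]]
    truth = GroundTruth(
        endo_u=endo_u,
        endo_v=endo_v,
        exo_u=exo_u,
        exo_v=exo_v,
        rho_endo=float(rho_endo),
        rho_exo=float(rho_exo),
        genes=genes,
        samples=list(attrs.index),
        planted_sets={
            "planted_endo": {"members": members, "end": spec.planted_set_end}
        },
    )
    return ExpressionProfile(values, attrs), truth


# ----------------------------------------------------------------------
# probe-level chips
# ----------------------------------------------------------------------

@dataclass
class ChipPair:
    reference: ProbeChip
    target: ProbeChip
    distortion: np.ndarray   # true additive spatial artifact (log2 scale)


def generate_probe_chip(
    side: int = 200,
    artifact: str = "gradient",
    seed: int = 0,
    noise_sd: float = 0.05,
    amplitude: float = 1.0,
    subarray_size: int = 50,
    probes_per_set: int = 11,
) -> ChipPair:
    """Reference chip plus a spatially distorted target on the same grid.

    Intensities are log2 scale.  ``artifact`` is 'none' (target == reference
    up to noise), 'gradient' (additive trend along rows, emulating uneven
    hybridization) or 'blotch' (a localized additive bump, emulating a
    washing defect).
    """
    if side < subarray_size:
        raise ValueError(f"side {side} smaller than subarray size {subarray_size}")
    if artifact not in ("none", "gradient", "blotch"):
        raise ValueError(f"unknown artifact {artifact!r}")
    rng = default_rng(seed)
    n = side * side
    n_sets = n // probes_per_set
    ids = np.array([f"ps{i:06d}" for i in range(n_sets)])
    assign = np.full(n, "", dtype="U12")
    order = rng.permutation(n)
    used = order[: n_sets * probes_per_set]
    assign[used] = np.repeat(ids, probes_per_set)

    base = np.empty(n)
    base[used] = np.repeat(rng.normal(8.0, 1.5, n_sets), probes_per_set)
    leftover = order[n_sets * probes_per_set:]
    base[leftover] = rng.normal(8.0, 1.5, len(leftover))
    probe_eff = rng.normal(0.0, 0.5, n)
    ref = (base + probe_eff).reshape(side, side)

    if artifact == "none":
        dist = np.zeros((side, side))
    elif artifact == "gradient":
        dist = amplitude * np.linspace(-1.0, 1.0, side)[:, None] * np.ones((1, side))
    else:  # blotch
        r0, c0 = rng.integers(0, side, 2)
        rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        sigma = side / 6.0
        dist = amplitude * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))

    target_vals = ref + dist
    if noise_sd > 0:
        target_vals = target_vals + noise_sd * rng.standard_normal((side, side))

    probeset_map = assign.reshape(side, side)
    return ChipPair(
        reference=ProbeChip(ref, probeset_map),
        target=ProbeChip(target_vals, probeset_map),
        distortion=dist,
    )


# ----------------------------------------------------------------------
# gene sets
# ----------------------------------------------------------------------

def generate_genesets(
    truth: GroundTruth,
    n_null_sets: int = 100,
    set_size: int | None = None,
    seed: int = 0,
):
    """Planted extreme set plus uniformly drawn null sets over the universe."""
    from .enrichment import GeneSetCollection

    universe = list(truth.genes)
    if not universe:
        raise ValueError("empty gene universe")
    if set_size is None:
        set_size = len(next(iter(truth.planted_sets.values()))["members"])
    if set_size <= 0:
        raise ValueError("set_size must be positive")
    if set_size > len(universe):
        raise ValueError("set_size exceeds the gene universe")
    rng = default_rng(seed)
    sets = {name: list(rec["members"]) for name, rec in truth.planted_sets.items()}
    for i in range(n_null_sets):
        sets[f"null_{i:03d}"] = list(
            rng.choice(universe, size=set_size, replace=False)
        )
    return GeneSetCollection(sets=sets, universe=universe)


# ----------------------------------------------------------------------
# promoters
# ----------------------------------------------------------------------

_ALPHABET = np.array(list("ACGT"))


def step_planting_rates(
    n_genes: int, top: int = 200, p_top: float = 0.9, p_background: float = 0.05
) -> np.ndarray:
    """Insertion probability per descending-loading rank: high for the top genes."""
    rates = np.full(n_genes, p_background)
    rates[:top] = p_top
    return rates


def generate_promoters(
    truth: GroundTruth,
    motif,
    promoter_length: int = 200,
    planting_rate_by_rank: np.ndarray | None = None,
    seed: int = 0,
    loading: np.ndarray | None = None,
) -> dict[str, str]:
    """Random promoters with motif sites planted at one loading extreme.

    Genes are ranked by ``loading`` (default: the planted endogenous gene
    eigenvector), descending; the gene at rank i receives one consensus
    site with probability ``planting_rate_by_rank[i]``.  Background is
    i.i.d. uniform A/C/G/T.  Records the genes that actually received a
    site in ``truth.planted_motif_genes``.
    """
    from .motif import PWM

    if not isinstance(motif, PWM):
        raise TypeError("motif must be a PWM")
    if motif.length > promoter_length:
        raise ValueError("motif longer than the promoter")
    g = len(truth.genes)
    if loading is None:
        loading = truth.endo_u
    if planting_rate_by_rank is None:
        planting_rate_by_rank = step_planting_rates(g)
    planting_rate_by_rank = np.asarray(planting_rate_by_rank, dtype=float)
    if len(planting_rate_by_rank) != g:
        raise ValueError("planting_rate_by_rank must have one entry per gene")
    if ((planting_rate_by_rank < 0) | (planting_rate_by_rank > 1)).any():
        raise ValueError("planting rates must be probabilities")

    rng = default_rng(seed)
    order = np.argsort(-loading, kind="stable")  # descending
    promoters: dict[str, str] = {}
    planted: list[str] = []
    site = np.array(list(motif.consensus))
    for rank, gi in enumerate(order):
        gene = truth.genes[gi]
        seq = rng.choice(_ALPHABET, size=promoter_length)
        if rng.random() < planting_rate_by_rank[rank]:
            pos = int(rng.integers(0, promoter_length - motif.length + 1))
            seq[pos: pos + motif.length] = site
            planted.append(gene)
        promoters[gene] = "".join(seq)
    truth.planted_motif_genes = planted
    # return in universe order for deterministic serialization
    return {gene: promoters[gene] for gene in truth.genes}
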