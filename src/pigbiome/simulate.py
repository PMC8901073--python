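"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates the study design it stands in for: 17 piglets in
three diet arms (white 5, traditional 6, oil 6) sampled at four timepoints
(days 1, 12, 26, 58; weaning at day 26), 68 samples in total. Counts come
from a logistic-normal/multinomial model: per-taxon latent log-abundances
are baseline + treatment effect + timepoint effect + per-pig random effect
+ stationary AR(1) noise across the pig's timepoints, mapped through a
softmax to a composition and sampled multinomially at a log-normal library
size. Pig effects and autocorrelation therefore enter additively on the
log scale, exactly the dependence structure the repeated-measures models
assume, which keeps parameter recovery well-posed.

The default taxon panel is the 46 distinct core lineages of the study it
emulates, with baseline log-abundances set from their published average
counts, giving a realistic rank-abundance shape; the default timepoint
effects encode each taxon's published pre-to-post-weaning shift and the
default treatment effects a modest Firmicutes enrichment (oil > traditional
> white), reproducing the observed F:B ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import substream
from .containers import (PERIOD_OF_TIMEPOINT, RANKS, TIMEPOINTS, TREATMENTS,
                         OtuTable, validate_metadata)
from .qc import ReadRecord
from .reference import load_core_taxa_reference, load_growth_summary_reference

#: Floor count used as a taxon's baseline in the period where the published
#: core lists do not report it (present but rare).
_RARE_BASELINE_COUNT = 5.0

DEFAULT_GROUP_SIZES = {"white": 5, "traditional": 6, "oil": 6}

#: Default Firmicutes log-fold enrichments per diet arm.
DEFAULT_TREATMENT_MULTIPLIERS = {"white": 1.0, "traditional": 1.15,
                                 "oil": 1.4}

READ_CLASSES = ("clean", "long_low_run", "low_fraction", "contains_N")


def default_taxon_panel() -> pd.DataFrame:
    """The 46 distinct reference lineages with per-period baselines.

    Columns: the six ranks, ``baseline_pre``/``baseline_post`` (natural-log
    average counts, floored at a small constant where a period lacks the
    taxon) and the derived per-timepoint log effects.
    """
    ref = load_core_taxa_reference()
    key = ref[list(RANKS)].agg(";".join, axis=1)
    panel = {}
    for (lineage, period), avg in zip(
            zip(key, ref["period"]), ref["avg_counts"]):
        panel.setdefault(lineage, {})[period] = float(avg)
    rows = []
    for lineage, by_period in panel.items():
        pre = by_period.get("pre", _RARE_BASELINE_COUNT)
        post = by_period.get("post", _RARE_BASELINE_COUNT)
        rows.append(lineage.split(";") + [math.log(pre), math.log(post)])
    df = pd.DataFrame(rows, columns=list(RANKS) + ["baseline_pre",
                                                   "baseline_post"])
    df.index = [f"taxon_{i + 1:03d}" for i in range(len(df))]
    return df


def random_taxon_panel(n_taxa: int, seed: int = 0,
                       sigma_log_abundance: float = 1.5) -> pd.DataFrame:
    """A synthetic taxon panel with a log-normal rank-abundance shape.

    Useful for calibration studies needing more taxa than the 46-lineage
    reference panel. Phyla rotate through the five major gut phyla so
    phylum-level operations (aggregation, F:B) stay meaningful; pre and
    post baselines are equal (no weaning shift).
    """
    rng = substream(seed, "taxon_panel")
    phyla = ["Firmicutes", "Bacteroidetes", "Proteobacteria",
             "Actinobacteria", "Fusobacteria"]
    base = rng.normal(math.log(200.0), sigma_log_abundance, n_taxa)
    rows = []
    for i in range(n_taxa):
        ph = phyla[i % len(phyla)]
        rows.append(["Bacteria", ph, f"{ph}_class", f"{ph}_order",
                     f"family_{i + 1}", f"genus_{i + 1}",
                     base[i], base[i]])
    df = pd.DataFrame(rows, columns=list(RANKS) + ["baseline_pre",
                                                   "baseline_post"])
    df.index = [f"taxon_{i + 1:04d}" for i in range(n_taxa)]
    return df


@dataclass
class SimParams:
    """Study-design and variance parameters for the generator.

    ``sigma_pig``, ``sigma_noise`` and ``rho`` are free parameters (the
    study reports no variance components); defaults are moderate values
    typical of log-scale 16S count variation.
    """

    n_pigs: int = 17
    group_sizes: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    timepoints: tuple = TIMEPOINTS
    sigma_pig: float = 0.3
    sigma_noise: float = 0.6
    rho: float = 0.4
    library_size_mu: float = math.log(85_000.0)
    library_size_sigma: float = 0.4
    read_length: int = 250
    seed: int = 42
    taxa: pd.DataFrame | None = None
    treatment_effects: pd.DataFrame | None = None  # taxa x treatments
    timepoint_effects: pd.DataFrame | None = None  # taxa x timepoints
    #: per-arm Firmicutes fold change used when treatment_effects is None
    treatment_multipliers: dict | None = None

    def __post_init__(self) -> None:
        if abs(self.rho) >= 1:
            raise ValueError("|rho| must be < 1")
        if self.sigma_pig < 0 or self.sigma_noise < 0:
            raise ValueError("standard deviations must be >= 0")
        if sum(self.group_sizes.values()) != self.n_pigs:
            raise ValueError(
                f"group sizes {self.group_sizes} do not sum to "
                f"n_pigs={self.n_pigs}")
        if self.taxa is None:
            self.taxa = default_taxon_panel()
        if not np.isfinite(
                self.taxa[["baseline_pre", "baseline_post"]].to_numpy()
        ).all():
            raise ValueError("baseline log-abundances must be finite")
        if self.timepoint_effects is None:
            shift = self.taxa["baseline_post"] - self.taxa["baseline_pre"]
            self.timepoint_effects = pd.DataFrame(
                {tp: (shift if PERIOD_OF_TIMEPOINT[tp] == "post" else 0.0)
                 for tp in self.timepoints}, index=self.taxa.index)
        if self.treatment_effects is None:
            mult = self.treatment_multipliers or DEFAULT_TREATMENT_MULTIPLIERS
            is_firm = (self.taxa["phylum"] == "Firmicutes").to_numpy()
            self.treatment_effects = pd.DataFrame(
                {t: np.where(is_firm, math.log(mult.get(t, 1.0)), 0.0)
                 for t in self.group_sizes},
                index=self.taxa.index)


def generate_design(params: SimParams) -> pd.DataFrame:
    """Sample metadata: one sample per pig x timepoint, pigs nested in
    treatments (default 17 pigs x 4 timepoints = 68 samples)."""
    rows = []
    for treatment, size in params.group_sizes.items():
        for i in range(size):
            pig = f"{treatment}_p{i + 1}"
            for tp in params.timepoints:
                rows.append((f"{pig}_{tp}", pig, treatment, tp))
    meta = pd.DataFrame(rows, columns=["sample", "pig", "treatment",
                                       "timepoint"]).set_index("sample")
    return validate_metadata(meta)


def _softmax(latent: np.ndarray) -> np.ndarray:
    z = latent - latent.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def expected_compositions(params: SimParams) -> pd.DataFrame:
    """Noise-free softmax composition per treatment x timepoint cell."""
    cols = {}
    base = params.taxa["baseline_pre"].to_numpy()
    for t in params.group_sizes:
        for tp in params.timepoints:
            latent = (base
                      + params.treatment_effects[t].to_numpy()
                      + params.timepoint_effects[tp].to_numpy())
            cols[(t, tp)] = _softmax(latent[:, None])[:, 0]
    return pd.DataFrame(cols, index=params.taxa.index)


def true_fb(params: SimParams) -> pd.DataFrame:
    """True F:B ratio of the noise-free composition per treatment x period."""
    comp = expected_compositions(params)
    firm = comp.loc[params.taxa["phylum"] == "Firmicutes"].sum()
    bact = comp.loc[params.taxa["phylum"] == "Bacteroidetes"].sum()
    fb = (firm / bact).rename("true_FB").reset_index()
    fb.columns = ["treatment", "timepoint", "true_FB"]
    fb["period"] = fb["timepoint"].map(PERIOD_OF_TIMEPOINT)
    return fb.groupby(["treatment", "period"], as_index=False)[
        "true_FB"].mean()


def _ar1_noise(rng: np.random.Generator, n_series: int, n_times: int,
               sigma: float, rho: float) -> np.ndarray:
    """Stationary AR(1) draws, marginal sd constant across timepoints."""
    e = np.empty((n_series, n_times))
    e[:, 0] = rng.normal(0.0, sigma, n_series)
    step_sd = sigma * math.sqrt(1.0 - rho ** 2)
    for t in range(1, n_times):
        e[:, t] = rho * e[:, t - 1] + rng.normal(0.0, step_sd, n_series)
    return e


def generate_otu_table(design: pd.DataFrame, params: SimParams
                       ) -> tuple[OtuTable, dict]:
    """Simulate counts for every sample in the design.

    Returns the table and a truth bundle with per-sample library sizes
    (equal to the emitted column sums by construction), per-pig/taxon
    random effects, the AR(1) noise, the full latent log-abundance matrix
    and the true cell-level F:B ratios.
    """
    rng = substream(params.seed, "otu_table")
    taxa = params.taxa
    n_taxa = len(taxa)
    tp_order = {tp: i for i, tp in enumerate(params.timepoints)}
    pigs = list(pd.unique(design["pig"]))

    pig_effects = pd.DataFrame(
        rng.normal(0.0, params.sigma_pig, (len(pigs), n_taxa)),
        index=pigs, columns=taxa.index)

    latent = pd.DataFrame(index=taxa.index, columns=design.index,
                          dtype=float)
    noise = pd.DataFrame(index=taxa.index, columns=design.index, dtype=float)
    base = taxa["baseline_pre"].to_numpy()
    for pig in pigs:
        samples = design.index[design["pig"] == pig]
        samples = samples[np.argsort(
            [tp_order[design.loc[s, "timepoint"]] for s in samples])]
        e = _ar1_noise(rng, n_taxa, len(samples), params.sigma_noise,
                       params.rho)
        for j, s in enumerate(samples):
            tp = design.loc[s, "timepoint"]
            treatment = design.loc[s, "treatment"]
            lam = (base
                   + params.treatment_effects[treatment].to_numpy()
                   + params.timepoint_effects[tp].to_numpy()
                   + pig_effects.loc[pig].to_numpy()
                   + e[:, j])
            if not np.isfinite(lam).all():
                bad = taxa.index[~np.isfinite(lam)][0]
                raise ValueError(f"non-finite latent abundance for {bad}")
            latent[s] = lam
            noise[s] = e[:, j]

    library_sizes = pd.Series(
        np.round(rng.lognormal(params.library_size_mu,
                               params.library_size_sigma,
                               len(design.index))).astype(np.int64),
        index=design.index, name="library_size")
    comp = _softmax(latent.to_numpy())
    counts = np.column_stack([
        rng.multinomial(library_sizes.iloc[j], comp[:, j])
        for j in range(comp.shape[1])
    ])
    table = OtuTable(
        counts=pd.DataFrame(counts, index=taxa.index, columns=design.index),
        lineages=taxa[list(RANKS)],
        metadata=design[["pig", "treatment", "timepoint"]],
    )
    truth = {
        "library_sizes": library_sizes,
        "pig_effects": pig_effects,
        "noise": noise,
        "latent": latent,
        "treatment_effects": params.treatment_effects,
        "timepoint_effects": params.timepoint_effects,
        "true_fb": true_fb(params),
    }
    return table, truth


# ----------------------------------------------------------- responses

def simulate_response(design: pd.DataFrame, mu: float = 0.0,
                      treatment_effects: dict | None = None,
                      timepoint_effects: dict | None = None,
                      sigma_pig: float = 0.3, sigma_noise: float = 0.6,
                      rho: float = 0.4,
                      rng: np.random.Generator | None = None,
                      seed: int = 0) -> pd.Series:
    """A single scalar response per sample drawn exactly from the
    repeated-measures model (used for parameter-recovery checks)."""
    if rng is None:
        rng = substream(seed, "response")
    treatment_effects = treatment_effects or {}
    timepoint_effects = timepoint_effects or {}
    tp_order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    y = pd.Series(index=design.index, dtype=float)
    for pig in pd.unique(design["pig"]):
        samples = design.index[design["pig"] == pig]
        samples = samples[np.argsort(
            [tp_order[design.loc[s, "timepoint"]] for s in samples])]
        e = _ar1_noise(rng, 1, len(samples), sigma_noise, rho)[0]
        u = rng.normal(0.0, sigma_pig)
        for j, s in enumerate(samples):
            y[s] = (mu + u + e[j]
                    + treatment_effects.get(design.loc[s, "treatment"], 0.0)
                    + timepoint_effects.get(design.loc[s, "timepoint"], 0.0))
    return y


# --------------------------------------------------------------- reads

def _class_counts(violation_mix: dict, n_reads: int) -> dict:
    unknown = set(violation_mix) - set(READ_CLASSES)
    if unknown:
        raise ValueError(f"unknown read classes: {sorted(unknown)}")
    total = sum(violation_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"violation_mix must sum to 1, got {total}")
    counts = {c: int(math.floor(violation_mix.get(c, 0.0) * n_reads))
              for c in READ_CLASSES}
    short = n_reads - sum(counts.values())
    for c in READ_CLASSES:
        if short == 0:
            break
        if violation_mix.get(c, 0.0) > 0:
            counts[c] += 1
            short -= 1
    return counts


def generate_reads(n_reads: int, params: SimParams,
                   violation_mix: dict | None = None,
                   threshold: int = 19, max_bad_run: int = 3,
                   min_fraction: float = 0.75,
                   seed: int | None = None
                   ) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Reads constructed to fall unambiguously into QC outcome classes.

    Classes: ``clean`` (all high quality, kept), ``long_low_run`` (an
    over-long low-quality run halfway through, truncation fails the length
    fraction), ``low_fraction`` (the run sits just under the fraction
    boundary), ``contains_N`` (an uncalled base in otherwise clean
    sequence). The manifest labels each read with its class and whether the
    filter should keep it.
    """
    rng = substream(params.seed if seed is None else seed, "reads")
    violation_mix = violation_mix or {"clean": 1.0}
    counts = _class_counts(violation_mix, n_reads)
    L = params.read_length
    run_len = max_bad_run + 1
    reads, manifest = [], []
    order = rng.permutation(
        [c for c in READ_CLASSES for _ in range(counts[c])])
    for i, cls in enumerate(order):
        bases = rng.choice(list("ACGT"), L)
        qual = np.full(L, 40)
        kept = cls == "clean"
        if cls == "long_low_run":
            start = L // 2
            qual[start:start + run_len] = 10
        elif cls == "low_fraction":
            start = int(min_fraction * L) - run_len  # fraction just below cut
            qual[start:start + run_len] = 10
        elif cls == "contains_N":
            bases[L // 2] = "N"
        reads.append(ReadRecord(f"read_{i + 1}", "".join(bases), qual))
        manifest.append((f"read_{i + 1}", cls, kept))
    return reads, pd.DataFrame(manifest,
                               columns=["read_id", "class", "expected_kept"])


# -------------------------------------------------------------- growth

def generate_growth_table(group_means: dict | None = None,
                          sd: float = 0.5,
                          mortality_probs: dict | None = None,
                          n_per_group: dict | None = None,
                          seed: int = 0,
                          max_resample: int = 1000) -> pd.DataFrame:
    """Per-piglet body weights and survival for the growth analysis.

    Defaults reproduce the reference cohort: group mean weights at days
    1/26/58 and mortality risks taken from the published group summary,
    full group sizes (57/68/72). Weights are Gaussian around the group
    means; draws violating positivity or within-piglet monotonicity are
    resampled. Piglets that die pre-weaning lack both later weights.
    """
    ref = load_growth_summary_reference()
    ref = ref[ref["cohort"] == "all"].set_index("group")
    if group_means is None:
        group_means = {g: tuple(ref.loc[g, ["bw_d1", "bw_d26", "bw_d58"]])
                       for g in ref.index}
    if n_per_group is None:
        n_per_group = {g: int(ref.loc[g, "n"]) for g in group_means}
    if mortality_probs is None:
        mortality_probs = {
            g: (float(ref.loc[g, "deaths_pre"] / ref.loc[g, "n"]),
                float(ref.loc[g, "deaths_post"] / ref.loc[g, "n"]))
            for g in group_means}
    for g, means in group_means.items():
        if min(means) <= 0:
            raise ValueError(f"group {g}: means must be positive")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = substream(seed, "growth")
    rows = []
    for g, (m1, m26, m58) in group_means.items():
        p_pre, p_post = mortality_probs.get(g, (0.0, 0.0))
        for i in range(n_per_group[g]):
            for _ in range(max_resample):
                bw = rng.normal([m1, m26, m58], sd)
                if bw[0] > 0 and bw[0] < bw[1] < bw[2]:
                    break
            else:
                raise RuntimeError(
                    f"could not draw monotone weights for group {g}; "
                    "sd too large relative to mean spacing")
            alive_pre = rng.random() >= p_pre
            alive_post = alive_pre and rng.random() >= p_post
            rows.append({
                "pig": f"{g}_{i + 1}", "group": g,
                "bw_d1": bw[0],
                "bw_d26": bw[1] if alive_pre else np.nan,
                "bw_d58": bw[2] if alive_post else np.nan,
                "alive_pre": alive_pre, "alive_post": alive_post,
            })
    return pd.DataFrame(rows)
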