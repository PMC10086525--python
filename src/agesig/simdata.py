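"""Synthetic study generator emulating a two-strain immune-aging design.

The generator produces the four kinds of inputs the analysis consumes:

* an RNA-seq-like count study — negative-binomial counts over a grid of
  (strain, tissue) strata sampled at a few ages, with a small set of planted
  "conserved aging genes" whose mean shifts log-linearly with age in every
  stratum, and optional strain-specific effects;
* regulatory data — per-sample peak intervals on a synthetic chromosome,
  TF footprint calls with purity scores where designated "aging TFs" land
  preferentially inside age-opening peaks in old groups, and per-base cut-site
  counts with Gaussian-shaped enrichment around footprints;
* flow-cytometry-like cell-composition percentages with linear age trends;
* a variance-components dataset for PVCA recovery (features as sums of
  random factor effects plus residual noise).

Every generator is fully determined by ``SimConfig.seed``; ground truth is
recorded in :class:`SimTruth` so that recovery tests can score the pipeline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from agesig.errors import ConfigError

STRATUM_SEP = ":"


def stratum_label(strain: str, tissue: str) -> str:
    return f"{strain}{STRATUM_SEP}{tissue}"


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the design of the real study: 2 strains (a long-lived and
    a short-lived one) x 4 tissues/cell types, young and old animals, with a
    5-gene conserved activation signature planted at log2 fold change 2 over
    the age span. ``dispersion`` fixes a single NB dispersion for all genes;
    when ``None``, per-gene dispersions are drawn from a gamma with shape
    ``dispersion_shape`` and mean ``dispersion_mean`` (defaults give the
    typical bulk RNA-seq range around 0.1).
    """

    seed: int = 0
    strains: Sequence[str] = ("B6", "NZO")
    tissues: Sequence[str] = ("PBL", "spleen", "naiveCD8", "memCD8")
    ages_months: Sequence[float] = (3.0, 18.0)
    replicates_per_age: int = 5
    n_genes: int = 5000
    planted_conserved: Mapping[str, float] = field(
        default_factory=lambda: {g: 2.0 for g in ("Jun", "Junb", "Fos", "Fosb", "Maff")}
    )
    planted_strain_specific: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    dispersion: float | None = None
    dispersion_shape: float = 2.0
    dispersion_mean: float = 0.1
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    baseline_log2_mean_range: tuple[float, float] = (0.0, 9.0)  # log2 CPM units

    # regulatory data
    chrom: str = "chrS"
    chrom_length: int = 10_000_000
    n_peaks: int = 1000
    peak_width: int = 400
    peak_jitter: int = 25
    sample_peak_presence: float = 0.8
    frac_opening: float = 0.1
    frac_closing: float = 0.1
    tf_names: Sequence[str] = tuple(f"TF{i:02d}" for i in range(1, 13))
    aging_tfs: Mapping[str, float] = field(default_factory=lambda: {"JunFos": 3.0})
    aging_tf_opening_prob: float = 0.9
    footprints_per_group: int = 3000
    footprint_width: int = 20
    purity_beta: tuple[float, float] = (8.0, 2.0)
    cut_background_rate: float = 0.2
    cut_enrichment_amplitude: float = 3.0
    cut_enrichment_sd: float = 15.0
    cut_signal_strata: Sequence[tuple[str, str]] | None = None  # default: first stratum

    # cell composition: cell type -> (intercept %, slope % per month)
    composition_trends: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "naiveCD8": (45.0, -1.2),
            "memCD8": (15.0, 1.0),
            "B": (30.0, -0.3),
            "monocytes": (10.0, 0.5),
        }
    )
    composition_noise_sd: float = 1.5

    # variance-components dataset: factor -> levels, factor -> sigma^2
    variance_design: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {"tissue": ("T1", "T2", "T3"), "strain": ("S1", "S2")}
    )
    variance_components: Mapping[str, float] = field(
        default_factory=lambda: {"tissue": 0.6, "strain": 0.3}
    )
    residual_variance: float = 0.1
    n_variance_features: int = 500
    variance_replicates: int = 4

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed: must be an integer")
        if len(self.strains) < 1 or len(set(self.strains)) != len(self.strains):
            raise ConfigError("strains: must be nonempty and unique")
        if len(self.tissues) < 1 or len(set(self.tissues)) != len(self.tissues):
            raise ConfigError("tissues: must be nonempty and unique")
        ages = list(self.ages_months)
        if len(set(ages)) < 2 or any(a <= 0 for a in ages):
            raise ConfigError("ages_months: need >= 2 distinct positive ages")
        if self.replicates_per_age < 2:
            raise ConfigError("replicates_per_age: must be >= 2")
        if self.n_genes < 1:
            raise ConfigError("n_genes: must be >= 1")
        planted = set(self.planted_conserved)
        for strain, effects in self.planted_strain_specific.items():
            if strain not in self.strains:
                raise ConfigError(f"planted_strain_specific: unknown strain {strain!r}")
            overlap = planted & set(effects)
            if overlap:
                raise ConfigError(
                    f"planted_strain_specific: genes also planted as conserved: {sorted(overlap)}"
                )
        for name, eff in self.planted_conserved.items():
            if not np.isfinite(eff):
                raise ConfigError(f"planted_conserved: non-finite effect for {name!r}")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ConfigError("dispersion: must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigError("library_size_range: must be positive and ordered")
        if self.chrom_length <= 0:
            raise ConfigError("chrom_length: must be positive")
        n_slots = self.chrom_length // (2 * self.peak_width)
        if self.n_peaks > n_slots:
            raise ConfigError(
                f"n_peaks: {self.n_peaks} peaks do not fit on a {self.chrom_length} bp "
                f"chromosome at width {self.peak_width}"
            )
        if not 0 <= self.sample_peak_presence <= 1:
            raise ConfigError("sample_peak_presence: must be in [0, 1]")
        if self.frac_opening + self.frac_closing > 1:
            raise ConfigError("frac_opening + frac_closing: must be <= 1")
        roster = len(self.tf_names) + len(self.aging_tfs)
        for tf, mult in self.aging_tfs.items():
            if mult <= 0:
                raise ConfigError(f"aging_tfs: multiplier for {tf!r} must be > 0")
        if sum(self.aging_tfs.values()) >= roster:
            raise ConfigError("aging_tfs: multipliers too large for the roster size")
        if self.composition_noise_sd < 0:
            raise ConfigError("composition_noise_sd: must be >= 0")
        for factor, s2 in self.variance_components.items():
            if factor not in self.variance_design:
                raise ConfigError(f"variance_components: unknown factor {factor!r}")
            if s2 < 0:
                raise ConfigError(f"variance_components: sigma^2 for {factor!r} must be >= 0")
        if self.residual_variance < 0:
            raise ConfigError("residual_variance: must be >= 0")

    # ------------------------------------------------------------------
    @property
    def strata(self) -> list[tuple[str, str]]:
        return [(s, t) for s in self.strains for t in self.tissues]

    def gene_ids(self) -> list[str]:
        planted = list(self.planted_conserved)
        for effects in self.planted_strain_specific.values():
            planted.extend(effects)
        n_null = self.n_genes - len(planted)
        if n_null < 0:
            raise ConfigError("n_genes: smaller than the number of planted genes")
        return planted + [f"g{i:05d}" for i in range(n_null)]


@dataclass
class SimTruth:
    """Ground truth of a synthetic dataset.

    ``effects`` holds the true log2 fold change over the min->max age span per
    gene (rows) per stratum (columns). ``variance_fractions`` are the true
    per-factor fractions of total variance; ``tf_multipliers`` records the
    old-group share multiplier per TF (1.0 = not an aging TF).
    """

    effects: pd.DataFrame | None = None
    planted_sets: dict[str, list[str]] = field(default_factory=dict)
    variance_fractions: dict[str, float] | None = None
    tf_multipliers: dict[str, float] | None = None
    composition_slopes: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# expression study


def generate_study(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate the count study: (counts, samples, truth).

    Counts for gene g in sample i of a stratum are NB with mean

        ``lib_i * 2^(b_g + f(age_i) * log2fc_{g,stratum}) / 1e6``

    where ``b_g`` is the baseline log2 CPM, ``f(age) = (age - age_min) /
    (age_max - age_min)``, and dispersion ``phi_g``; null genes have zero
    effect. Identical configs and seeds give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    n_genes = len(genes)
    ages = sorted(config.ages_months)
    age_min, age_max = ages[0], ages[-1]
    span = age_max - age_min

    baseline = rng.uniform(*config.baseline_log2_mean_range, size=n_genes)
    if config.dispersion is not None:
        phi = np.full(n_genes, float(config.dispersion))
    else:
        scale = config.dispersion_mean / config.dispersion_shape
        phi = rng.gamma(config.dispersion_shape, scale, size=n_genes)
        phi = np.maximum(phi, 1e-6)

    strata = [stratum_label(s, t) for s, t in config.strata]
    effects = pd.DataFrame(0.0, index=genes, columns=strata)
    for g, fc in config.planted_conserved.items():
        effects.loc[g, :] = fc
    for strain, strain_effects in config.planted_strain_specific.items():
        cols = [stratum_label(strain, t) for t in config.tissues]
        for g, fc in strain_effects.items():
            effects.loc[g, cols] = fc

    sample_rows = []
    count_cols = {}
    for strain, tissue in config.strata:
        label = stratum_label(strain, tissue)
        beta = effects[label].to_numpy()
        for age in ages:
            frac = (age - age_min) / span
            for rep in range(config.replicates_per_age):
                sid = f"{strain}_{tissue}_{age:g}m_r{rep + 1}"
                sex = "F" if rep % 2 == 0 else "M"
                lib = int(rng.integers(config.library_size_range[0],
                                       config.library_size_range[1] + 1))
                mu = lib * np.exp2(baseline + frac * beta) / 1e6
                n_param = 1.0 / phi
                p_param = n_param / (n_param + mu)
                count_cols[sid] = rng.negative_binomial(n_param, p_param)
                sample_rows.append((sid, strain, tissue, float(age), sex))

    counts = pd.DataFrame(count_cols, index=genes)
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "strain", "tissue", "age_months", "sex"]
    ).set_index("sample_id")

    truth = SimTruth(
        effects=effects,
        planted_sets={
            "conserved": list(config.planted_conserved),
            **{
                f"strain_specific_{s}": list(e)
                for s, e in config.planted_strain_specific.items()
            },
        },
    )
    return counts, samples, truth


# ---------------------------------------------------------------------------
# regulatory data


def _tf_probabilities(config: SimConfig, old: bool) -> tuple[list[str], np.ndarray]:
    """TF sampling probabilities for a group.

    Young groups draw TFs uniformly from the roster. In old groups each aging
    TF's share is multiplied by its configured factor (so its old/young share
    ratio equals the multiplier exactly) and the remainder is spread uniformly
    over the other TFs.
    """
    roster = list(config.tf_names) + list(config.aging_tfs)
    k = len(roster)
    probs = np.full(k, 1.0 / k)
    if old:
        aging_mass = 0.0
        for i, tf in enumerate(roster):
            if tf in config.aging_tfs:
                probs[i] = config.aging_tfs[tf] / k
                aging_mass += probs[i]
        others = [i for i, tf in enumerate(roster) if tf not in config.aging_tfs]
        probs[others] = (1.0 - aging_mass) / len(others)
    return roster, probs


def generate_regulatory(
    config: SimConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict[tuple, np.ndarray], SimTruth]:
    """Simulate peaks, footprints, and cut-site signal.

    Returns ``(per_sample_peaks, footprints, cut_signal, truth)``:

    * ``per_sample_peaks``: sample id -> BED-like DataFrame (chrom, start,
      end, name, support=1), sorted, 0-based half-open;
    * ``footprints``: DataFrame with chrom/start/end/tf/purity plus the group
      columns strain/tissue/age_months and a ``region`` column naming the true
      underlying peak region (with its opening/closing/stable status encoded
      in the region name);
    * ``cut_signal``: (strain, tissue, age) -> per-base int32 cut counts for
      the strata selected by ``cut_signal_strata`` (default: first stratum).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ages = sorted(config.ages_months)
    age_young, age_old = ages[0], ages[-1]

    # non-overlapping true peak regions on a slot grid (guarantees sortedness
    # and leaves gaps so jittered per-sample intervals cannot collide)
    slot = 2 * config.peak_width + 2 * config.peak_jitter + 10
    n_slots = (config.chrom_length - 2 * slot) // slot
    if config.n_peaks > n_slots:
        raise ConfigError("n_peaks: chromosome too short for the requested peak count")
    slots = np.sort(rng.choice(n_slots, size=config.n_peaks, replace=False))
    starts = slot + slots * slot
    ends = starts + config.peak_width

    n_open = int(round(config.frac_opening * config.n_peaks))
    n_close = int(round(config.frac_closing * config.n_peaks))
    status = np.array(["stable"] * config.n_peaks, dtype=object)
    special = rng.choice(config.n_peaks, size=n_open + n_close, replace=False)
    status[special[:n_open]] = "opening"
    status[special[n_open:]] = "closing"
    region_names = [f"region_{i:04d}_{status[i]}" for i in range(config.n_peaks)]

    # per-sample jittered peak intervals
    per_sample_peaks: dict[str, pd.DataFrame] = {}
    for strain, tissue in config.strata:
        for age in ages:
            for rep in range(config.replicates_per_age):
                sid = f"{strain}_{tissue}_{age:g}m_r{rep + 1}"
                present = rng.random(config.n_peaks) < config.sample_peak_presence
                jit_s = rng.integers(-config.peak_jitter, config.peak_jitter + 1,
                                     size=config.n_peaks)
                jit_e = rng.integers(-config.peak_jitter, config.peak_jitter + 1,
                                     size=config.n_peaks)
                s = np.maximum(starts + jit_s, 0)[present]
                e = np.minimum(ends + jit_e, config.chrom_length)[present]
                keep = e > s
                df = pd.DataFrame({
                    "chrom": config.chrom,
                    "start": s[keep],
                    "end": e[keep],
                    "name": np.asarray(region_names, dtype=object)[present][keep],
                    "support": 1,
                })
                per_sample_peaks[sid] = df.sort_values(["start", "end"]).reset_index(drop=True)

    # footprints per pooled group (strain, tissue, age)
    opening_idx = np.flatnonzero(status == "opening")
    all_idx = np.arange(config.n_peaks)
    fp_rows = []
    for strain, tissue in config.strata:
        for age in ages:
            old = age == age_old
            roster, probs = _tf_probabilities(config, old=old)
            tf_draw = rng.choice(len(roster), size=config.footprints_per_group, p=probs)
            region_draw = np.empty(config.footprints_per_group, dtype=int)
            for i, ti in enumerate(tf_draw):
                tf = roster[ti]
                if old and tf in config.aging_tfs and len(opening_idx) and (
                    rng.random() < config.aging_tf_opening_prob
                ):
                    region_draw[i] = rng.choice(opening_idx)
                else:
                    region_draw[i] = rng.choice(all_idx)
            offset = rng.integers(0, config.peak_width - config.footprint_width,
                                  size=config.footprints_per_group)
            fp_start = starts[region_draw] + offset
            purity = rng.beta(*config.purity_beta, size=config.footprints_per_group)
            purity = np.minimum(purity, 1.0)
            for i in range(config.footprints_per_group):
                fp_rows.append((
                    config.chrom, int(fp_start[i]), int(fp_start[i]) + config.footprint_width,
                    roster[tf_draw[i]], float(purity[i]),
                    strain, tissue, float(age), region_names[region_draw[i]],
                ))
    footprints = pd.DataFrame(
        fp_rows,
        columns=["chrom", "start", "end", "tf", "purity",
                 "strain", "tissue", "age_months", "region"],
    ).sort_values(["strain", "tissue", "age_months", "start"]).reset_index(drop=True)

    # dense cut-site signal for the selected strata
    cut_strata = config.cut_signal_strata
    if cut_strata is None:
        cut_strata = [config.strata[0]]
    cut_signal: dict[tuple, np.ndarray] = {}
    half = int(3 * config.cut_enrichment_sd)
    offsets = np.arange(-half, half + 1)
    bump = config.cut_enrichment_amplitude * np.exp(
        -0.5 * (offsets / config.cut_enrichment_sd) ** 2
    )
    for strain, tissue in cut_strata:
        if (strain, tissue) not in config.strata:
            raise ConfigError(f"cut_signal_strata: unknown stratum {(strain, tissue)!r}")
        for age in ages:
            signal = rng.poisson(config.cut_background_rate,
                                 size=config.chrom_length).astype(np.int32)
            grp = footprints[(footprints["strain"] == strain)
                             & (footprints["tissue"] == tissue)
                             & (footprints["age_months"] == age)]
            centers = ((grp["start"] + grp["end"]) // 2).to_numpy()
            for c in centers:
                lo, hi = c - half, c + half + 1
                if lo < 0 or hi > config.chrom_length:
                    continue
                signal[lo:hi] += rng.poisson(bump).astype(np.int32)
            cut_signal[(strain, tissue, float(age))] = signal

    roster_all = list(config.tf_names) + list(config.aging_tfs)
    truth = SimTruth(
        tf_multipliers={tf: float(config.aging_tfs.get(tf, 1.0)) for tf in roster_all},
    )
    return per_sample_peaks, footprints, cut_signal, truth


# ---------------------------------------------------------------------------
# cell composition


def generate_composition(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate per-animal cell-type percentages with linear age trends.

    percent = intercept + slope * age + N(0, sd), clipped to [0, 100];
    sibling cell types are simulated independently (they need not sum to 100,
    mirroring independent gating).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    ages = sorted(config.ages_months)
    rows = []
    for strain, tissue in config.strata:
        for age in ages:
            for rep in range(config.replicates_per_age):
                animal = f"{strain}_{tissue}_{age:g}m_a{rep + 1}"
                sex = "F" if rep % 2 == 0 else "M"
                for cell_type, (intercept, slope) in config.composition_trends.items():
                    pct = intercept + slope * age
                    if config.composition_noise_sd > 0:
                        pct += rng.normal(0.0, config.composition_noise_sd)
                    pct = float(np.clip(pct, 0.0, 100.0))
                    rows.append((animal, strain, tissue, float(age), sex, cell_type, pct))
    table = pd.DataFrame(
        rows,
        columns=["animal_id", "strain", "tissue", "age_months", "sex", "cell_type", "percent"],
    )
    truth = SimTruth(
        composition_slopes={ct: s for ct, (_, s) in config.composition_trends.items()}
    )
    return table, truth


# ---------------------------------------------------------------------------
# variance-components dataset


def generate_variance_dataset(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a balanced dataset with known variance fractions for PVCA.

    Samples form the full crossing of all factor levels, replicated
    ``variance_replicates`` times. Each feature is the sum of one random
    Gaussian effect per factor level plus residual noise; the recorded truth
    fractions are sigma^2_k / (sum_k sigma^2_k + sigma^2_res).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    factors = list(config.variance_design)
    level_grid = list(itertools.product(*(config.variance_design[f] for f in factors)))
    assignments = []
    for rep in range(config.variance_replicates):
        for combo in level_grid:
            assignments.append((*combo, rep))
    factor_table = pd.DataFrame(assignments, columns=[*factors, "replicate"])
    factor_table.index = [f"s{i:03d}" for i in range(len(factor_table))]
    factor_table = factor_table.drop(columns="replicate")
    n_samples = len(factor_table)

    level_codes = {
        f: pd.Categorical(factor_table[f], categories=config.variance_design[f]).codes
        for f in factors
    }
    n_features = config.n_variance_features
    data = np.zeros((n_features, n_samples))
    for f in factors:
        s2 = config.variance_components.get(f, 0.0)
        n_levels = len(config.variance_design[f])
        u = rng.normal(0.0, np.sqrt(s2), size=(n_features, n_levels))
        data += u[:, level_codes[f]]
    data += rng.normal(0.0, np.sqrt(config.residual_variance), size=(n_features, n_samples))

    features = pd.DataFrame(
        data, index=[f"f{i:04d}" for i in range(n_features)], columns=factor_table.index
    )
    total = sum(config.variance_components.get(f, 0.0) for f in factors) + config.residual_variance
    if total <= 0:
        raise ConfigError("variance_components: total variance must be > 0")
    fractions = {f: config.variance_components.get(f, 0.0) / total for f in factors}
    fractions["residual"] = config.residual_variance / total
    truth = SimTruth(variance_fractions=fractions)
    return features, factor_table, truth
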