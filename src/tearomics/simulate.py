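"""Synthetic tear-proteome cohort generation.

The real severity-graded cohort behind this analysis is clinical data and
not redistributable, so every downstream stage is exercised on simulated
cohorts that reproduce the statistical structure the analysis assumes:

* right-skewed, wide-ranged peak areas (log-normal on the raw scale),
* abundance-dependent missingness (low-abundance proteins drop below the
  detection limit more often — the standard LC-MS
  missing-not-at-random mechanism),
* occasional protein-inference quantifications recorded as 0,
* named contaminant proteins (keratins, dermcidins, trypsins) so the
  preprocessing name filter has something to remove,
* optional planted severity effects: per-protein log2 fold changes of the
  group mean relative to a baseline severity level.

Default cohort composition follows the study design this package targets:
31 / 126 / 76 patients at MGD levels 2 / 3 / 4 and ~2000 protein features.

All randomness flows from ``SimConfig.seed`` through ``numpy``
``SeedSequence`` spawning; identical configs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from tearomics.containers import ClinicalTable, ProteinQuantTable, VALID_LEVELS

# Contaminants a tear LC-MS run typically carries: skin keratins and
# dermcidins, plus the digestion reagent trypsins.  Keratin 18 is on the
# preprocessing keep-list and is injected as a probe for that rule.
DEFAULT_CONTAMINANTS: dict[str, str] = {
    "P04264": "Keratin, type II cytoskeletal 1",
    "P05783": "Keratin, type I cytoskeletal 18",
    "P81605": "Dermcidin",
    "P07477": "Trypsin-1",
    "Q9BYT5": "Putative trypsin-6",
}


@dataclass(frozen=True)
class MissingnessSpec:
    """Logistic detection curve on the log2-abundance scale.

    detect(z) = 1 / (1 + exp(-slope * (z - midpoint)))

    ``midpoint`` is the log2 abundance at 50% detection; ``slope`` > 0
    makes detection increase with abundance (missing-not-at-random).
    Set ``midpoint`` far below the abundance range to disable missingness.
    """

    midpoint: float = 10.0
    slope: float = 0.8

    def detection_probability(self, log2_abundance: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        return expit(self.slope * (np.asarray(log2_abundance, dtype=float) - self.midpoint))


@dataclass(frozen=True)
class PlantedEffect:
    """A per-protein severity effect on the log2 scale.

    ``log2_fc_per_level`` maps severity level -> log2 shift of that
    level's group mean relative to the baseline level.  Levels absent
    from the map shift by 0; at least one cohort level must have shift 0
    so a baseline exists.
    """

    protein_index: int
    log2_fc_per_level: dict[int, float] = field(default_factory=dict)

    def shift_for(self, level: int) -> float:
        return float(self.log2_fc_per_level.get(int(level), 0.0))


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    ``base_abundance`` = (meanlog, sdlog) of per-protein mean log2
    abundance; ``noise_sd`` is the within-protein between-patient spread
    (log2 units).  Defaults emulate a 233-patient severity-graded tear
    cohort with peak areas spanning several orders of magnitude.
    """

    counts_per_level: dict[int, int] = field(default_factory=lambda: {2: 31, 3: 126, 4: 76})
    n_proteins: int = 2000
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    contaminant_names: list[str] = field(default_factory=lambda: list(DEFAULT_CONTAMINANTS.values()))
    inference_zero_rate: float = 0.01
    base_abundance: tuple[float, float] = (15.0, 2.5)
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not self.counts_per_level:
            raise ValueError("counts_per_level must not be empty")
        for level, count in self.counts_per_level.items():
            if int(level) not in VALID_LEVELS:
                raise ValueError(f"invalid severity level {level}")
            if count <= 0:
                raise ValueError("all level counts must be > 0")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be > 0")
        if not 0.0 <= self.inference_zero_rate <= 1.0:
            raise ValueError("inference_zero_rate must be in [0, 1]")
        if self.base_abundance[1] <= 0:
            raise ValueError("sdlog must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        levels = sorted(int(lv) for lv in self.counts_per_level)
        for eff in self.planted_effects:
            if not 0 <= eff.protein_index < self.n_proteins:
                raise ValueError(f"planted effect references unknown protein {eff.protein_index}")
            if all(eff.shift_for(lv) != 0.0 for lv in levels):
                raise ValueError("planted effect has no baseline level with shift 0")


def apply_severity_effects(
    log_abundance: np.ndarray,
    labels: ClinicalTable,
    effects: list[PlantedEffect],
) -> np.ndarray:
    """Shift group means of affected proteins on the log2 scale.

    Rows follow ``labels`` order; returns a new matrix, input untouched.
    """
    out = np.array(log_abundance, dtype=float, copy=True)
    if not effects:
        return out
    levels = labels.levels
    n_proteins = out.shape[1]
    for eff in effects:
        if not 0 <= eff.protein_index < n_proteins:
            raise ValueError(f"planted effect references unknown protein {eff.protein_index}")
        shifts = np.array([eff.shift_for(lv) for lv in levels])
        out[:, eff.protein_index] += shifts
    return out


def apply_missingness(
    raw: np.ndarray, spec: MissingnessSpec, seed: int | np.random.Generator
) -> np.ndarray:
    """Censor entries below the stochastic detection limit (-> NaN).

    Each strictly-positive entry is kept with the logistic detection
    probability evaluated at its own log2 abundance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = np.asarray(raw, dtype=float)
    if np.any(raw <= 0):
        raise ValueError("apply_missingness expects strictly positive raw abundances")
    detect_p = spec.detection_probability(np.log2(raw))
    out = raw.copy()
    out[rng.random(raw.shape) >= detect_p] = np.nan
    return out


def generate_cohort(config: SimConfig) -> tuple[ProteinQuantTable, ClinicalTable]:
    """Simulate one cohort: quantification table + severity labels.

    Deterministic given ``config`` (including its seed).  Contaminant
    proteins are appended as extra columns drawn from the same abundance
    model, carrying the configured names.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_mean, rng_noise, rng_missing, rng_zero = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    levels_sorted = sorted(int(lv) for lv in config.counts_per_level)
    level_vec = np.concatenate(
        [np.full(config.counts_per_level[lv], lv, dtype=int) for lv in levels_sorted]
    )
    n_samples = level_vec.size
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    clinical = ClinicalTable(pd.DataFrame({"sample_id": sample_ids, "mgd_level": level_vec}))

    n_contam = len(config.contaminant_names)
    n_total = config.n_proteins + n_contam
    meanlog, sdlog = config.base_abundance
    protein_means = rng_mean.normal(meanlog, sdlog, size=n_total)
    log2 = protein_means[None, :] + rng_noise.normal(0.0, config.noise_sd, size=(n_samples, n_total))
    log2[:, : config.n_proteins] = apply_severity_effects(
        log2[:, : config.n_proteins], clinical, config.planted_effects
    )

    raw = np.exp2(log2)
    raw = apply_missingness(raw, config.missingness, rng_missing)
    if config.inference_zero_rate > 0:
        detected = ~np.isnan(raw)
        zero_mask = detected & (rng_zero.random(raw.shape) < config.inference_zero_rate)
        raw[zero_mask] = 0.0

    accessions = [f"SIM{i + 1:05d}" for i in range(config.n_proteins)]
    names = [f"Simulated tear protein {i + 1}" for i in range(config.n_proteins)]
    contam_acc = []
    for cname in config.contaminant_names:
        match = [acc for acc, nm in DEFAULT_CONTAMINANTS.items() if nm == cname]
        contam_acc.append(match[0] if match else f"CON{len(contam_acc) + 1:05d}")
    values = pd.DataFrame(raw, index=pd.Index(sample_ids, name="sample_id"),
                          columns=accessions + contam_acc)
    name_series = pd.Series(names + list(config.contaminant_names),
                            index=accessions + contam_acc)
    return ProteinQuantTable(values, name_series), clinical


def config_to_json_dict(config: SimConfig) -> dict:
    """JSON-serializable view of a config (for run manifests)."""
    d = asdict(config)
    d["counts_per_level"] = {str(k): v for k, v in config.counts_per_level.items()}
    d["planted_effects"] = [
        {"protein_index": e.protein_index,
         "log2_fc_per_level": {str(k): v for k, v in e.log2_fc_per_level.items()}}
        for e in config.planted_effects
    ]
    return d


def config_from_json_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["counts_per_level"] = {int(k): int(v) for k, v in d["counts_per_level"].items()}
    d["planted_effects"] = [
        PlantedEffect(int(e["protein_index"]),
                      {int(k): float(v) for k, v in e["log2_fc_per_level"].items()})
        for e in d.get("planted_effects", [])
    ]
    d["missingness"] = MissingnessSpec(**d.get("missingness", {}))
    d["base_abundance"] = tuple(d.get("base_abundance", (15.0, 2.5)))
    return SimConfig(**d)
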