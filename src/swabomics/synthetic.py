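"""Synthetic longitudinal cohort generator with recorded ground truth.

Emulates the data structure of a two-cohort pregnancy swab study: subjects
sampled at up to five gestational-age windows; per-sample vaginal community
state types (CSTs) following a Markov chain over visits;
Dirichlet-multinomial species counts conditioned on CST; a log-scale
metabolome driven by a linear mixed model (CST offsets, gestational slope,
demographic effects, per-subject random intercept and slope); immune-marker
concentrations loading on designated metabolite features; raw
ambient-ionization spectra synthesized from feature intensities; and a
term/sPTB outcome whose odds increase with microbiome instability.  Every
generated quantity that downstream analyses try to recover is recorded in a
:class:`GroundTruth`.

All randomness flows from one integer seed through spawned substreams, one
per table, so adding a table does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from swabomics.containers import (
    ALL_CSTS,
    CST_TEMPLATES,
    FeatureMatrix,
    LDEPL_CSTS,
    RawSpectrum,
    dominance_of,
)

DEFAULT_SPECIES = (
    "Lactobacillus crispatus",
    "Lactobacillus gasseri",
    "Lactobacillus iners",
    "Gardnerella vaginalis",
    "Lactobacillus jensenii",
    "Bifidobacterium breve",
    "Lactobacillus vaginalis",
    "Atopobium vaginae",
    "Prevotella bivia",
    "Streptococcus agalactiae",
)

#: Gestational sampling windows (weeks): up to five visits per pregnancy.
DEFAULT_WINDOWS = ((8, 16), (16, 20), (20, 26), (26, 30), (30, 37))

DEFAULT_ETHNICITIES = ("Caucasian", "Asian", "Black")
DEFAULT_ETHNICITY_PROBS = (0.71, 0.07, 0.22)


def _default_species_profiles() -> dict[str, np.ndarray]:
    """Per-CST Dirichlet concentrations: sharp dominance of the template taxon.

    Concentration mass 0.8 on the dominant species (total concentration 50
    keeps profiles tight, as real CSTs are) and the remainder spread evenly.
    CST VII is dominated by a Lactobacillus outside the four named templates.
    """
    species = list(DEFAULT_SPECIES)
    dominant = dict(CST_TEMPLATES)
    dominant["VII"] = "Lactobacillus vaginalis"
    profiles = {}
    total = 50.0
    for cst in ALL_CSTS:
        conc = np.full(len(species), 0.2 * total / (len(species) - 1))
        conc[species.index(dominant[cst])] = 0.8 * total
        profiles[cst] = conc
    return profiles


def _default_transition_matrix(persistence: float = 0.85) -> np.ndarray:
    n = len(ALL_CSTS)
    mat = np.full((n, n), (1 - persistence) / (n - 1))
    np.fill_diagonal(mat, persistence)
    return mat


def _default_feature_mz(n_features: int, seed: int = 12345) -> np.ndarray:
    """Distinct, well-spaced m/z values across the 50-1000 Da scan range."""
    rng = np.random.default_rng(seed)
    base = np.linspace(120.0, 900.0, n_features)
    jitter = rng.uniform(-2.0, 2.0, n_features)
    return np.sort(base + jitter)


def _default_effect_table(n_features: int, n_informative: int = 30,
                          effect_size: float = 1.0,
                          ethnicities=DEFAULT_ETHNICITIES,
                          seed: int = 54321) -> pd.DataFrame:
    """Per-feature fixed effects; the first ``n_informative`` features carry
    an LDEPL offset of ``effect_size`` on the log scale, the rest are null."""
    rng = np.random.default_rng(seed)
    tab = pd.DataFrame(index=pd.RangeIndex(n_features, name="feature"))
    for cst in ALL_CSTS:
        tab[f"cst_{cst}"] = 0.0
    informative = np.arange(min(n_informative, n_features))
    for cst in LDEPL_CSTS:
        tab.loc[informative, f"cst_{cst}"] = effect_size
    tab["ga_slope"] = 0.0
    tab.loc[informative[: n_informative // 3], "ga_slope"] = rng.choice(
        [-0.03, 0.03], size=len(informative[: n_informative // 3])
    )
    tab["age"] = 0.0
    tab["bmi"] = 0.0
    for eth in ethnicities:
        tab[f"eth_{eth}"] = 0.0
    tab["baseline"] = 10.0
    return tab


def _default_immune_loadings(n_features: int) -> pd.DataFrame:
    """Markers x features loading matrix: three markers, each driven by two
    of the informative features."""
    load = pd.DataFrame(
        0.0,
        index=["IL1b", "MBL", "IL8"],
        columns=pd.RangeIndex(n_features, name="feature"),
    )
    if n_features >= 6:
        load.loc["IL1b", [0, 1]] = 0.4
        load.loc["MBL", [2, 3]] = 0.4
        load.loc["IL8", [4, 5]] = 0.4
    return load


@dataclass
class CohortConfig:
    """Full parameterisation of one synthetic cohort."""

    n_subjects: int = 160
    visits_per_subject: int = 5
    gestation_windows: tuple = DEFAULT_WINDOWS
    cst_initial_probs: dict[str, float] = field(
        default_factory=lambda: {
            "I": 0.33, "II": 0.05, "III": 0.30, "IV": 0.15,
            "V": 0.08, "VI": 0.03, "VII": 0.06,
        }
    )
    cst_transition_matrix: np.ndarray = field(
        default_factory=_default_transition_matrix
    )
    species: tuple = DEFAULT_SPECIES
    species_profiles: dict[str, np.ndarray] = field(
        default_factory=_default_species_profiles
    )
    library_size: int = 10000
    n_features: int = 60
    feature_mz: np.ndarray | None = None
    effect_table: pd.DataFrame | None = None
    subject_sd_intercept: float = 0.5
    subject_sd_slope: float = 0.02
    noise_sd: float = 0.5
    ethnicities: tuple = DEFAULT_ETHNICITIES
    ethnicity_probs: tuple = DEFAULT_ETHNICITY_PROBS
    immune_loadings: pd.DataFrame | None = None
    immune_noise_sd: float = 0.3
    ptb_base_rate: float = 0.18
    instability_odds_multiplier: float = 2.0
    drift_amplitude: float = 0.0
    # spectrum synthesis
    spectrum_mz_range: tuple[float, float] = (50.0, 1000.0)
    spectrum_mz_step: float = 0.01
    spectrum_resolution: float = 30000.0
    spectrum_n_scans: int = 30
    spectrum_ppm_jitter: float = 0.0
    spectrum_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_mz is None:
            self.feature_mz = _default_feature_mz(self.n_features)
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        if self.effect_table is None:
            self.effect_table = _default_effect_table(
                self.n_features, ethnicities=self.ethnicities
            )
        if self.immune_loadings is None:
            self.immune_loadings = _default_immune_loadings(self.n_features)
        self.validate()

    def validate(self) -> None:
        if not (1 <= self.visits_per_subject <= 5):
            raise ValueError("visits_per_subject must be between 1 and 5")
        probs = np.array([self.cst_initial_probs.get(c, 0.0) for c in ALL_CSTS])
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("cst_initial_probs must be a probability vector")
        tm = np.asarray(self.cst_transition_matrix, dtype=float)
        if tm.shape != (len(ALL_CSTS), len(ALL_CSTS)):
            raise ValueError("transition matrix must be 7x7")
        if np.any(tm < 0) or np.any(np.abs(tm.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        for cst in ALL_CSTS:
            if cst not in self.species_profiles:
                raise ValueError(f"missing species profile for CST {cst}")
            if len(self.species_profiles[cst]) != len(self.species):
                raise ValueError("species profile length mismatch")
        for sd in (self.subject_sd_intercept, self.subject_sd_slope,
                   self.noise_sd, self.immune_noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if np.any(self.feature_mz <= 0):
            raise ValueError("feature m/z must be strictly positive")
        if len(np.unique(self.feature_mz)) != len(self.feature_mz):
            raise ValueError("feature m/z must be unique")
        if len(self.feature_mz) != self.n_features:
            raise ValueError("feature_mz length must equal n_features")
        if not (0 <= self.ptb_base_rate <= 1):
            raise ValueError("ptb_base_rate must be a probability")
        unknown = set(self.immune_loadings.columns) - set(range(self.n_features))
        if unknown:
            raise ValueError(f"immune loadings reference unknown features: {unknown}")


@dataclass
class GroundTruth:
    """Everything the downstream analyses attempt to recover."""

    effect_table: pd.DataFrame
    cst_per_sample: pd.Series
    immune_loadings: pd.DataFrame
    subject_unstable: pd.Series
    subject_ptb_prob: pd.Series
    random_intercepts: pd.Series | None = None
    random_slopes: pd.Series | None = None
    drift_factors: pd.Series | None = None


@dataclass
class SyntheticCohort:
    covariates: pd.DataFrame
    species_counts: pd.DataFrame
    metabolome: FeatureMatrix
    immune: pd.DataFrame
    truth: GroundTruth
    config: CohortConfig
    spectra: dict[str, list[RawSpectrum]] | None = None


def _streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


STREAM_NAMES = (
    "covariates", "cst", "species", "metabolome", "immune",
    "outcome", "spectra", "drift",
)


def generate_cohort(config: CohortConfig, with_spectra: bool = False) -> SyntheticCohort:
    """Generate one cohort; deterministic given ``config.seed``."""
    rngs = _streams(config.seed, STREAM_NAMES)

    covariates, cst_per_sample = _generate_covariates_and_cst(config, rngs)
    species = generate_species_counts(cst_per_sample, config, rngs["species"])
    metabolome, truth = generate_metabolome(
        covariates, cst_per_sample, config, rngs["metabolome"]
    )
    immune = generate_immune_panel(metabolome, config, rngs["immune"])
    _draw_outcomes(covariates, cst_per_sample, config, rngs["outcome"], truth)
    cohort = SyntheticCohort(
        covariates=covariates,
        species_counts=species,
        metabolome=metabolome,
        immune=immune,
        truth=truth,
        config=config,
    )
    if with_spectra:
        cohort.spectra = {
            sid: synthesize_spectra(
                np.exp(metabolome.values.loc[sid].to_numpy()), config, rngs["spectra"]
            )
            for sid in metabolome.sample_ids
        }
    return cohort


def _generate_covariates_and_cst(config: CohortConfig, rngs):
    rng_cov = rngs["covariates"]
    rng_cst = rngs["cst"]
    windows = config.gestation_windows[: config.visits_per_subject]
    tm = np.asarray(config.cst_transition_matrix, dtype=float)
    init = np.array([config.cst_initial_probs.get(c, 0.0) for c in ALL_CSTS])
    rows = []
    cst_labels = {}
    for i in range(config.n_subjects):
        subject = f"S{i:04d}"
        age = float(np.clip(rng_cov.normal(32.0, 5.0), 18, 45))
        bmi = float(np.clip(rng_cov.normal(25.0, 4.0), 16, 48))
        eth = rng_cov.choice(config.ethnicities, p=config.ethnicity_probs)
        state = int(rng_cst.choice(len(ALL_CSTS), p=init))
        for v, (lo, hi) in enumerate(windows):
            ga = float(rng_cov.uniform(lo, hi))
            sid = f"{subject}_V{v + 1}"
            rows.append(
                {
                    "sample_id": sid, "subject_id": subject, "visit": v + 1,
                    "gestational_age": ga, "maternal_age": age, "bmi": bmi,
                    "ethnicity": eth,
                }
            )
            cst_labels[sid] = ALL_CSTS[state]
            state = int(rng_cst.choice(len(ALL_CSTS), p=tm[state]))
    covariates = pd.DataFrame(rows).set_index("sample_id")
    # gestational ages strictly increase per subject because windows are
    # ordered; guard against boundary-equal draws
    covariates = covariates.sort_index()
    cst = pd.Series(cst_labels, name="cst").loc[covariates.index]
    covariates["cst"] = cst
    return covariates, cst


def _draw_outcomes(covariates, cst_per_sample, config, rng, truth: GroundTruth):
    dom = cst_per_sample.map(dominance_of)
    unstable = {}
    for subject, rows in covariates.groupby("subject_id"):
        states = set(dom.loc[rows.index])
        unstable[subject] = len(states) > 1
    unstable = pd.Series(unstable, name="unstable")
    base_logit = np.log(config.ptb_base_rate / (1 - config.ptb_base_rate)) \
        if 0 < config.ptb_base_rate < 1 else (-np.inf if config.ptb_base_rate == 0 else np.inf)
    logit = base_logit + np.log(config.instability_odds_multiplier) * unstable.astype(float)
    prob = 1.0 / (1.0 + np.exp(-logit))
    draw = rng.uniform(size=len(prob)) < prob
    outcome = pd.Series(
        np.where(draw, "sPTB", "term"), index=unstable.index, name="outcome"
    )
    covariates["outcome"] = covariates["subject_id"].map(outcome)
    truth.subject_unstable = unstable
    truth.subject_ptb_prob = pd.Series(prob, index=unstable.index)


def generate_species_counts(
    cst_per_sample: pd.Series, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Dirichlet-multinomial species counts given each sample's CST."""
    unknown = set(cst_per_sample.unique()) - set(ALL_CSTS)
    if unknown:
        raise ValueError(f"unknown CST label(s): {sorted(unknown)}")
    counts = np.empty((len(cst_per_sample), len(config.species)), dtype=int)
    for i, cst in enumerate(cst_per_sample):
        conc = np.asarray(config.species_profiles[cst], dtype=float)
        if np.count_nonzero(conc) == 1:
            p = (conc > 0).astype(float)  # degenerate point mass
        else:
            p = rng.dirichlet(conc)
        counts[i] = rng.multinomial(config.library_size, p)
    return pd.DataFrame(
        counts, index=cst_per_sample.index, columns=list(config.species)
    )


def generate_metabolome(
    covariates: pd.DataFrame,
    cst_per_sample: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[FeatureMatrix, GroundTruth]:
    """Log-scale metabolome from the generative linear mixed model.

    log-intensity = baseline + CST offset + slope * GA + age/BMI/ethnicity
    effects + subject random intercept + subject random slope * GA + noise.
    """
    eff = config.effect_table
    subjects = covariates["subject_id"].unique()
    n_samp, n_feat = len(covariates), config.n_features
    u = rng.normal(0.0, config.subject_sd_intercept, size=(len(subjects), n_feat))
    v = rng.normal(0.0, config.subject_sd_slope, size=(len(subjects), n_feat))
    subj_ix = pd.Index(subjects).get_indexer(covariates["subject_id"])
    ga = covariates["gestational_age"].to_numpy()[:, None]

    fixed = np.tile(eff["baseline"].to_numpy(), (n_samp, 1))
    cst_cols = {c: eff[f"cst_{c}"].to_numpy() for c in ALL_CSTS}
    for i, cst in enumerate(cst_per_sample.loc[covariates.index]):
        fixed[i] += cst_cols[cst]
    fixed += ga * eff["ga_slope"].to_numpy()[None, :]
    fixed += covariates["maternal_age"].to_numpy()[:, None] * eff["age"].to_numpy()[None, :]
    fixed += covariates["bmi"].to_numpy()[:, None] * eff["bmi"].to_numpy()[None, :]
    for eth in config.ethnicities:
        mask = (covariates["ethnicity"] == eth).to_numpy()[:, None]
        fixed += mask * eff[f"eth_{eth}"].to_numpy()[None, :]

    log_int = (
        fixed
        + u[subj_ix]
        + v[subj_ix] * ga
        + rng.normal(0.0, config.noise_sd, size=(n_samp, n_feat))
    )
    values = pd.DataFrame(
        log_int, index=covariates.index, columns=[float(m) for m in config.feature_mz]
    )
    matrix = FeatureMatrix(values=values, log_scale=True)
    truth = GroundTruth(
        effect_table=eff.copy(),
        cst_per_sample=cst_per_sample.copy(),
        immune_loadings=config.immune_loadings.copy(),
        subject_unstable=pd.Series(dtype=bool),
        subject_ptb_prob=pd.Series(dtype=float),
        random_intercepts=pd.Series(u[:, 0], index=subjects),
        random_slopes=pd.Series(v[:, 0], index=subjects),
    )
    return matrix, truth


def generate_immune_panel(
    metabolome: FeatureMatrix, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Immune marker concentrations loading on designated log-features.

    log(marker + 1) = loadings . log-features + noise; concentrations are
    returned on the natural scale and clipped at 0 (assay floor).
    """
    load = config.immune_loadings
    feats = metabolome.values.to_numpy()
    if not metabolome.log_scale:
        feats = np.log(np.maximum(feats, 0) + 1)
    lin = feats[:, load.columns.to_numpy()] @ load.to_numpy().T
    lin = lin + rng.normal(0.0, config.immune_noise_sd, size=lin.shape)
    conc = np.clip(np.exp(lin) - 1.0, 0.0, None)
    return pd.DataFrame(conc, index=metabolome.sample_ids, columns=load.index)


def synthesize_spectra(
    feature_intensities: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
) -> list[RawSpectrum]:
    """Synthesize raw scans: one Gaussian per feature plus baseline noise.

    Peak width follows the configured resolving power (sigma = m/z / R /
    2.355); apex height is proportional to the feature intensity; each scan
    applies independent ppm jitter to peak centres and additive half-normal
    baseline noise.
    """
    lo, hi = config.spectrum_mz_range
    if np.any(config.feature_mz < lo) or np.any(config.feature_mz > hi):
        raise ValueError("feature m/z outside the configured scan range")
    axis = np.arange(lo, hi + config.spectrum_mz_step / 2, config.spectrum_mz_step)
    scans = []
    for s in range(config.spectrum_n_scans):
        inten = np.zeros_like(axis)
        for mz0, height in zip(config.feature_mz, feature_intensities):
            if height <= 0:
                continue
            centre = mz0 * (1 + rng.normal(0, config.spectrum_ppm_jitter) * 1e-6)
            sigma = centre / config.spectrum_resolution / 2.355
            sel = np.abs(axis - centre) < 6 * sigma
            inten[sel] += height * np.exp(
                -0.5 * ((axis[sel] - centre) / sigma) ** 2
            )
        if config.spectrum_noise_sd > 0:
            inten += np.abs(rng.normal(0, config.spectrum_noise_sd, axis.size))
        scans.append(RawSpectrum(mz=axis.copy(), intensity=inten, scan_index=s))
    return scans


# ---------------------------------------------------------------------------
# run-order structure: reference samples and drift


def add_reference_samples(
    matrix: FeatureMatrix,
    sr_spacing: int = 8,
    dilution_factors: tuple = (0.125, 0.25, 0.5, 0.75, 1.0),
    rng: np.random.Generator | None = None,
) -> FeatureMatrix:
    """Interleave pooled SR injections and an SR dilution series into a run.

    The SR sample is the mean of all study samples (natural scale); dilution
    samples scale it by the given factors and are placed at both ends of the
    run, as in a real acquisition.
    """
    if matrix.log_scale:
        raise ValueError("reference samples are built on the natural scale")
    study = matrix.values
    sr_profile = study.mean(axis=0)
    # the run opens with an SR injection, then the dilution series; study
    # samples follow with SR re-injections every ``sr_spacing`` positions and
    # the dilution series is repeated at the end of the run
    all_rows: list[tuple[str, pd.Series, str, float]] = [
        ("SR_000", sr_profile, "SR", np.nan)
    ]
    for f in dilution_factors:
        all_rows.append((f"DIL_start_{f}", sr_profile * f, "dilution", f))
    i_sr = 0
    for i, sid in enumerate(study.index):
        if i and i % sr_spacing == 0:
            i_sr += 1
            all_rows.append((f"SR_{i_sr:03d}", sr_profile, "SR", np.nan))
        all_rows.append((sid, study.loc[sid], "study", np.nan))
    i_sr += 1
    all_rows.append((f"SR_{i_sr:03d}", sr_profile, "SR", np.nan))
    for f in dilution_factors:
        all_rows.append((f"DIL_end_{f}", sr_profile * f, "dilution", f))
    values = pd.DataFrame(
        {sid: vals for sid, vals, _, _ in all_rows}
    ).T
    values.index.name = "sample_id"
    meta = pd.DataFrame(
        {
            "run_order": np.arange(len(all_rows)),
            "sample_role": [r for _, _, r, _ in all_rows],
            "dilution_factor": [d for _, _, _, d in all_rows],
        },
        index=values.index,
    )
    return FeatureMatrix(values=values, sample_meta=meta, polarity=matrix.polarity)


def inject_drift(
    matrix: FeatureMatrix,
    drift_amplitude: float | None = None,
    shape: str = "linear",
) -> tuple[FeatureMatrix, pd.Series]:
    """Multiply intensities by a smooth positive drift over injection order.

    ``shape='linear'`` declines from 1 to ``1 - amplitude`` across the run
    (amplitude 0.5 halves intensities by the end); ``shape='cosine'`` is a
    smooth dip and recovery.  Requires SR samples in the run so the drift
    can later be estimated and corrected; the applied per-sample factors are
    returned for round-trip checks.
    """
    if not (matrix.sample_role == "SR").any():
        raise ValueError("drift injection requires SR samples in the run")
    amp = 0.0 if drift_amplitude is None else float(drift_amplitude)
    order = matrix.run_order.to_numpy(dtype=float)
    x = (order - order.min()) / max(order.max() - order.min(), 1.0)
    if shape == "linear":
        g = 1.0 - amp * x
    elif shape == "cosine":
        g = 1.0 - amp * 0.5 * (1 - np.cos(2 * np.pi * x))
    else:
        raise ValueError(f"unknown drift shape {shape!r}")
    if np.any(g <= 0):
        raise ValueError("drift amplitude too large: factors must stay positive")
    out = matrix.copy()
    out.values.loc[:, :] = out.values.to_numpy() * g[:, None]
    factors = pd.Series(g, index=matrix.sample_ids, name="drift_factor")
    return out, factors
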