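"""Synthetic pooled-GWAS studies with known truth.

The generator emulates a two-group pooled-DNA case-control study on a
two-channel SNP array:

* per-marker allele-A frequencies drawn from a uniform common-variant
  range, with an optional set of effect markers whose case frequency is
  shifted by a fixed Δ;
* Hardy–Weinberg genotypes for the pool members and for a separately
  genotyped individual reference panel (the calibration / call-rate /
  accuracy-reference cohort);
* a per-marker amplification ratio k (log-uniform), so allele A of a
  heterozygote fluoresces k times brighter than allele B;
* pools built by partitioning each group's members into fixed, disjoint
  pools of equal size; the realised pool frequency is the members' mean
  A-dosage/2, perturbed by normal pool-construction error (CV-scaled) and
  an optional uniform bias, clamped to [0, 1];
* replicate arrays measuring each pool with lognormal multiplicative
  channel noise (mean 1, CV-parameterised) around expected signals
  a* = base·f·k and b* = base·(1−f).

Defaults mirror a realistic study: 6 pools of 50 individuals per group,
3 technical replicates per pool, a 100+100 reference panel, replicate
noise CV 10 % and construction CV 2 %.  Identical config + seed gives a
byte-identical file bundle.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import PoolDesign
from .errors import ConfigError
from .ingest import (
    write_annotation_table,
    write_design_table,
    write_genotype_table,
    write_intensity_table,
)

_CALL_BY_DOSE = np.array(["BB", "AB", "AA"])


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the generator.

    All coefficients of variation are unitless; ``base_intensity`` is in
    arbitrary fluorescence units.  ``effect_size`` is the difference in
    true allele-A frequency between the case and control groups at effect
    markers (case = control + Δ).
    """

    n_markers: int = 1000
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_individuals_per_group: int = 300
    n_pools_per_group: int = 6
    individuals_per_pool: int = 50
    replicates_per_pool: int = 3
    n_reference_individuals_per_group: int = 100
    k_low: float = 0.5
    k_high: float = 2.0
    n_effect_markers: int = 0
    effect_size: float = 0.0
    pool_construction_cv: float = 0.02
    replicate_noise_cv: float = 0.10
    pool_bias: float = 0.0
    nocall_rate: float = 0.01
    homozygote_leakage: float = 0.0
    base_intensity: float = 1000.0
    groups: tuple[str, str] = ("case", "control")
    seed: int = 0

    def validate(self) -> None:
        c = self
        if c.n_markers < 1:
            raise ConfigError("n_markers must be >= 1")
        if not 0.0 < c.maf_low <= c.maf_high <= 0.5:
            raise ConfigError("need 0 < maf_low <= maf_high <= 0.5")
        if c.n_pools_per_group * c.individuals_per_pool > c.n_individuals_per_group:
            raise ConfigError(
                "not enough individuals per group: "
                f"{c.n_pools_per_group} pools x {c.individuals_per_pool} "
                f"> {c.n_individuals_per_group}"
            )
        if c.n_pools_per_group < 2:
            raise ConfigError("need at least 2 pools per group")
        if c.replicates_per_pool < 1:
            raise ConfigError("need at least 1 replicate per pool")
        if not 0.0 < c.k_low <= c.k_high:
            raise ConfigError("need 0 < k_low <= k_high")
        if c.n_effect_markers < 0 or c.n_effect_markers > c.n_markers:
            raise ConfigError("n_effect_markers must be in [0, n_markers]")
        if c.n_effect_markers > 0 and not 0.0 < c.effect_size < 0.5:
            raise ConfigError("effect_size must be in (0, 0.5) when effect markers exist")
        for name in ("pool_construction_cv", "replicate_noise_cv", "nocall_rate",
                     "homozygote_leakage"):
            if getattr(c, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if c.base_intensity <= 0:
            raise ConfigError("base_intensity must be > 0")


@dataclass
class StudyBundle:
    """Everything one simulated study produces, truth included."""

    config: SimulationConfig
    design: PoolDesign
    annotation: pd.DataFrame
    genotypes: pd.DataFrame              # reference-panel calls
    individual_intensities: pd.DataFrame  # reference-panel signals
    pool_intensities: pd.DataFrame        # replicate-array signals
    sample_groups: pd.DataFrame           # reference sample -> group
    truth_markers: pd.DataFrame           # per-marker truth (freqs, k, effect flag)
    truth_pools: pd.DataFrame             # realised per-pool frequencies
    replicate_expected: pd.DataFrame      # noise-free expected replicate signals


# ---------------------------------------------------------------------------
# noise helpers


def _lognormal_factor(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with mean 1 and the requested CV."""
    if cv <= 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=shape)


def _marker_ids(n: int) -> np.ndarray:
    width = len(str(n))
    return np.array([f"rs{10 ** width + i}" for i in range(n)])


# ---------------------------------------------------------------------------
# genotype and intensity simulation


def simulate_genotypes(
    config: SimulationConfig,
    group: str,
    rng: np.random.Generator,
    freqs: np.ndarray,
    n_individuals: int | None = None,
    sample_prefix: str | None = None,
):
    """Hardy–Weinberg genotypes for one group's cohort.

    ``freqs`` holds the group's true allele-A frequency per marker.  Calls
    are drawn iid with P(AA) = p², P(AB) = 2p(1−p), P(BB) = (1−p)²;
    no-calls are injected at ``config.nocall_rate`` (the underlying dosage
    still drives the sample's intensities).

    Returns ``(genotype_frame, dosages, sample_ids)`` where ``dosages`` is
    the (n_markers, n_individuals) A-allele dosage matrix before no-call
    masking.
    """
    n = n_individuals if n_individuals is not None else config.n_reference_individuals_per_group
    prefix = sample_prefix if sample_prefix is not None else f"{group}_s"
    p = np.asarray(freqs, dtype=float)
    dosages = rng.binomial(2, p[:, None], size=(len(p), n))
    calls = _CALL_BY_DOSE[dosages].astype(object)
    if config.nocall_rate > 0:
        calls[rng.random(dosages.shape) < config.nocall_rate] = "NoCall"
    markers = _marker_ids(config.n_markers)
    samples = np.array([f"{prefix}{i + 1:04d}" for i in range(n)])
    frame = pd.DataFrame(
        {
            "marker_id": np.repeat(markers, n),
            "sample_id": np.tile(samples, len(p)),
            "call": calls.ravel(),
        }
    )
    return frame, dosages, samples


def simulate_individual_intensities(
    dosages: np.ndarray,
    k_true: np.ndarray,
    sample_ids: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Two-channel signals for individually assayed samples.

    For A-dosage d the expected signals are a* = base·(d/2)·k and
    b* = base·(1 − d/2); an optional ``homozygote_leakage`` fraction of
    the absent allele's share leaks into its channel.  Observed signals
    multiply the expectation by lognormal noise (CV =
    ``replicate_noise_cv``), so homozygote zero-channels stay zero.
    """
    d = np.asarray(dosages, dtype=float) / 2.0  # allele-A share in [0, 1]
    k = np.asarray(k_true, dtype=float)[:, None]
    lam = config.homozygote_leakage
    base = config.base_intensity
    a_exp = base * k * (d + lam * (1.0 - d))
    b_exp = base * ((1.0 - d) + lam * d)
    a = a_exp * _lognormal_factor(rng, config.replicate_noise_cv, d.shape)
    b = b_exp * _lognormal_factor(rng, config.replicate_noise_cv, d.shape)
    markers = _marker_ids(config.n_markers)
    return pd.DataFrame(
        {
            "marker_id": np.repeat(markers, d.shape[1]),
            "sample_id": np.tile(np.asarray(sample_ids), d.shape[0]),
            "signal_a": a.ravel(),
            "signal_b": b.ravel(),
        }
    )


def simulate_pools(
    dosages_by_group: dict[str, np.ndarray],
    k_true: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
):
    """Pool construction and replicate-array measurement.

    Each group's members are partitioned (without replacement, fixed for
    all markers — pools are physical) into ``n_pools_per_group`` pools of
    ``individuals_per_pool``.  The realised pool frequency is the members'
    mean A-dosage / 2, perturbed by normal construction error with
    sd = ``pool_construction_cv``·f, shifted by ``pool_bias`` and clamped
    to [0, 1].  Each pool is then measured on ``replicates_per_pool``
    arrays with lognormal channel noise.

    Returns ``(pool_intensities, design, truth_pools, replicate_expected)``.
    """
    markers = _marker_ids(config.n_markers)
    k = np.asarray(k_true, dtype=float)
    base = config.base_intensity
    npools, ipp, nrep = (
        config.n_pools_per_group,
        config.individuals_per_pool,
        config.replicates_per_pool,
    )

    pool_rows, truth_rows, expected_rows = [], [], []
    pool_to_group: dict[str, str] = {}
    replicate_to_pool: dict[str, str] = {}
    for group in config.groups:
        dos = dosages_by_group[group]
        perm = rng.permutation(dos.shape[1])[: npools * ipp]
        members = perm.reshape(npools, ipp)
        # (n_markers, npools): realised frequency of each physical pool
        f = dos[:, members].mean(axis=2) / 2.0
        if config.pool_construction_cv > 0:
            f = f + rng.normal(0.0, config.pool_construction_cv * f)
        f = np.clip(f + config.pool_bias, 0.0, 1.0)
        a_exp = base * f * k[:, None]
        b_exp = base * (1.0 - f)
        for j in range(npools):
            pool_id = f"{group}_p{j + 1}"
            pool_to_group[pool_id] = group
            truth_rows.append(
                pd.DataFrame(
                    {"marker_id": markers, "pool_id": pool_id, "pool_freq": f[:, j]}
                )
            )
            for r in range(nrep):
                rep_id = f"{pool_id}_r{r + 1}"
                replicate_to_pool[rep_id] = pool_id
                a = a_exp[:, j] * _lognormal_factor(rng, config.replicate_noise_cv, len(markers))
                b = b_exp[:, j] * _lognormal_factor(rng, config.replicate_noise_cv, len(markers))
                pool_rows.append(
                    pd.DataFrame(
                        {
                            "marker_id": markers,
                            "sample_id": rep_id,
                            "signal_a": a,
                            "signal_b": b,
                        }
                    )
                )
                expected_rows.append(
                    pd.DataFrame(
                        {
                            "marker_id": markers,
                            "replicate_id": rep_id,
                            "expected_a": a_exp[:, j],
                            "expected_b": b_exp[:, j],
                        }
                    )
                )
    design = PoolDesign(
        groups=config.groups,
        pool_to_group=pool_to_group,
        replicate_to_pool=replicate_to_pool,
    )
    return (
        pd.concat(pool_rows, ignore_index=True),
        design,
        pd.concat(truth_rows, ignore_index=True),
        pd.concat(expected_rows, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# whole-study generation


def generate_study(config: SimulationConfig, out_dir: str | Path | None = None) -> StudyBundle:
    """Generate a complete study; optionally write its file bundle.

    Identical ``config`` (seed included) gives byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_markers
    markers = _marker_ids(n)
    case, ctrl = config.groups

    # per-marker truth
    p_ctrl = rng.uniform(config.maf_low, config.maf_high, size=n)
    is_effect = np.zeros(n, dtype=bool)
    if config.n_effect_markers:
        is_effect[rng.choice(n, size=config.n_effect_markers, replace=False)] = True
    p_case = p_ctrl + np.where(is_effect, config.effect_size, 0.0)
    k_true = np.exp(rng.uniform(np.log(config.k_low), np.log(config.k_high), size=n))
    truth_markers = pd.DataFrame(
        {
            "marker_id": markers,
            "freq_case": p_case,
            "freq_control": p_ctrl,
            "k_true": k_true,
            "is_effect": is_effect,
        }
    )

    # individually genotyped reference panel (calibration + call rate + accuracy)
    geno_frames, inten_frames, group_rows = [], [], []
    for group, p in ((case, p_case), (ctrl, p_ctrl)):
        frame, dosages, samples = simulate_genotypes(config, group, rng, p)
        geno_frames.append(frame)
        inten_frames.append(
            simulate_individual_intensities(dosages, k_true, samples, config, rng)
        )
        group_rows.append(pd.DataFrame({"sample_id": samples, "group": group}))

    # pool members are a separate cohort of the stated size per group
    pool_dosages = {
        group: rng.binomial(2, p[:, None], size=(n, config.n_individuals_per_group))
        for group, p in ((case, p_case), (ctrl, p_ctrl))
    }
    pool_intensities, design, truth_pools, replicate_expected = simulate_pools(
        pool_dosages, k_true, config, rng
    )

    annotation = pd.DataFrame(
        {
            "marker_id": markers,
            "chromosome": [str(1 + i % 22) for i in range(n)],
            "position": [1000 * (i + 1) for i in range(n)],
            "is_rs": True,
        }
    )

    bundle = StudyBundle(
        config=config,
        design=design,
        annotation=annotation,
        genotypes=pd.concat(geno_frames, ignore_index=True),
        individual_intensities=pd.concat(inten_frames, ignore_index=True),
        pool_intensities=pool_intensities,
        sample_groups=pd.concat(group_rows, ignore_index=True),
        truth_markers=truth_markers,
        truth_pools=truth_pools,
        replicate_expected=replicate_expected,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


BUNDLE_FILES = {
    "pool_intensities": "pool_intensities.tsv",
    "individual_intensities": "individual_intensities.tsv",
    "genotypes": "genotypes.tsv",
    "annotation": "annotation.tsv",
    "design": "design.tsv",
    "sample_groups": "sample_groups.tsv",
    "truth_markers": "truth_markers.tsv",
    "truth_pools": "truth_pools.tsv",
    "config": "config.yaml",
}


def write_bundle(bundle: StudyBundle, out_dir: str | Path) -> None:
    """Write the study as the tab-delimited bundle the ingest module reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_intensity_table(bundle.pool_intensities, out / BUNDLE_FILES["pool_intensities"])
    write_intensity_table(
        bundle.individual_intensities, out / BUNDLE_FILES["individual_intensities"]
    )
    write_genotype_table(bundle.genotypes, out / BUNDLE_FILES["genotypes"])
    write_annotation_table(bundle.annotation, out / BUNDLE_FILES["annotation"])
    write_design_table(bundle.design, out / BUNDLE_FILES["design"])
    bundle.sample_groups.rename(
        columns={"sample_id": "Sample", "group": "Group"}
    ).to_csv(out / BUNDLE_FILES["sample_groups"], sep="\t", index=False, lineterminator="\n")
    bundle.truth_markers.rename(
        columns={
            "marker_id": "Marker",
            "freq_case": "TrueFreqCase",
            "freq_control": "TrueFreqControl",
            "k_true": "K_true",
            "is_effect": "IsEffect",
        }
    ).to_csv(
        out / BUNDLE_FILES["truth_markers"],
        sep="\t",
        index=False,
        float_format="%.10g",
        lineterminator="\n",
    )
    bundle.truth_pools.rename(
        columns={"marker_id": "Marker", "pool_id": "Pool", "pool_freq": "PoolFreq"}
    ).to_csv(
        out / BUNDLE_FILES["truth_pools"],
        sep="\t",
        index=False,
        float_format="%.10g",
        lineterminator="\n",
    )
    cfg = asdict(bundle.config)
    cfg["groups"] = list(cfg["groups"])
    with open(out / BUNDLE_FILES["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
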