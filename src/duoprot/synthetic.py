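"""Synthetic three-group proteomics datasets with left-censored missingness.

The generator emulates the statistical structure a label-free iBAQ
experiment hands to the analysis: log-normal protein intensities, a small
planted set of group-differential proteins, and intensity-dependent
(missing-not-at-random) dropout, where the probability that a cell is
detected follows a logistic curve in log2 intensity.  Low-abundance
proteins therefore go missing preferentially — the regime in which
downshifted-normal imputation is the appropriate model.

Defaults reproduce the scale of the study the pipeline targets: 26 samples
in groups of 11/6/9 (non-diabetic / pre-diabetic / type 2 diabetic), 3963
proteins of which roughly 52% survive the 90% group-validity filter, and 23
planted differential proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .matrix import GROUP_LABELS, GroupDesign, ProteinMatrix, empty_flags

DEFAULT_N_PER_GROUP = (11, 6, 9)


@dataclass(frozen=True)
class PlantedEffect:
    """A log2 mean shift applied to one protein in one group."""

    group: str
    effect_log2: float

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic dataset.

    ``base_mu``/``base_sigma`` set the log2-intensity location/spread of the
    protein baseline distribution; ``noise_sd`` is the per-cell log2
    measurement noise.  ``missing_slope``/``missing_mid`` parameterize the
    logistic detection curve P(detected | x) = expit(slope * (x - mid)) in
    log2 intensity, so the missing probability is strictly decreasing in
    intensity whenever slope > 0.  Defaults are calibrated so that the 90%
    group-validity filter retains ~2076 of 3963 proteins.
    """

    n_per_group: tuple[int, int, int] = DEFAULT_N_PER_GROUP
    n_proteins: int = 3963
    n_differential: int = 23
    effects: tuple[PlantedEffect, ...] | None = None
    effect_log2: float = 2.5
    base_mu: float = 25.0
    base_sigma: float = 2.0
    noise_sd: float = 0.5
    missing_slope: float = 1.0
    missing_mid: float = 23.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 3:
            raise ValueError("n_per_group must give counts for the N, P and D groups")
        if any(int(n) < 2 for n in self.n_per_group):
            raise ValueError(f"each group needs >= 2 samples, got {self.n_per_group}")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.n_differential < 0 or self.n_differential > self.n_proteins:
            raise ValueError("n_differential must be in [0, n_proteins]")
        if self.base_sigma <= 0:
            raise ValueError("base_sigma must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.missing_slope < 0:
            raise ValueError("missing_slope must be non-negative "
                             "(detection must not decrease with intensity)")
        if self.effects is not None and len(self.effects) != self.n_differential:
            raise ValueError("effects list length must equal n_differential")
        if abs(self.effect_log2) < 1e-12 and self.n_differential and self.effects is None:
            raise ValueError("effect_log2 must be non-zero for planted proteins")

    def resolved_effects(self) -> tuple[PlantedEffect, ...]:
        """Explicit per-planted-protein effects.

        When not given, planted proteins alternate between an up-shift in P
        and a down-shift in D (the two disease groups), mirroring the mix of
        pre-diabetes increases and T2D decreases the pipeline is meant to
        detect.
        """
        if self.effects is not None:
            return self.effects
        out = []
        for i in range(self.n_differential):
            if i % 2 == 0:
                out.append(PlantedEffect("D", -abs(self.effect_log2)))
            else:
                out.append(PlantedEffect("P", +abs(self.effect_log2)))
        return tuple(out)


@dataclass
class GroundTruth:
    """Everything an oracle test needs about the generated dataset."""

    planted_ids: list[str]
    effects: dict[str, PlantedEffect]
    true_group_means: pd.DataFrame  # planted proteins x groups, log2 units
    directions: pd.DataFrame  # planted proteins x contrasts, in {-1, 0, +1}
    latent_log2: pd.DataFrame  # full pre-missingness log2 matrix
    spec: SyntheticSpec = field(repr=False)

    def to_json_dict(self) -> dict:
        return {
            "planted_ids": self.planted_ids,
            "effects": {p: {"group": e.group, "effect_log2": e.effect_log2}
                        for p, e in self.effects.items()},
            "true_group_means": self.true_group_means.to_dict(orient="index"),
            "directions": self.directions.to_dict(orient="index"),
        }


CONTRASTS = ("N_vs_P", "N_vs_D", "P_vs_D")


def _directions(true_means: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for contrast in CONTRASTS:
        a, b = contrast.split("_vs_")
        out[contrast] = np.sign(true_means[b] - true_means[a]).astype(int)
    return pd.DataFrame(out, index=true_means.index)


def generate_dataset(spec: SyntheticSpec) -> tuple[ProteinMatrix, GroundTruth]:
    """Generate a proteins x samples matrix plus its ground truth.

    Latent log2 intensities are baseline + planted group shift + Gaussian
    noise; each cell is then detected with probability given by the logistic
    curve, independently.  The emitted matrix is on the linear iBAQ scale
    (2**log2) with NaN for non-detected cells, exactly what the
    proteinGroups reader would produce.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_base, rng_noise, rng_detect = (np.random.default_rng(s) for s in ss.spawn(3))

    n_n, n_p, n_d = (int(x) for x in spec.n_per_group)
    design = GroupDesign.from_pairs(
        [(f"N{i+1:02d}", "N") for i in range(n_n)]
        + [(f"P{i+1:02d}", "P") for i in range(n_p)]
        + [(f"D{i+1:02d}", "D") for i in range(n_d)]
    )
    n_samples = len(design.samples)
    labels = design.labels

    ids = pd.Index([f"PROT{i+1:05d}" for i in range(spec.n_proteins)],
                   name="Protein IDs")
    effects = spec.resolved_effects()
    planted_ids = [f"PROT{i+1:05d}" for i in range(spec.n_differential)]

    # Background baselines; planted proteins drawn from a moderately high,
    # well-detected band (+1 sd, narrow spread) so the panel, like a real
    # biomarker panel, survives the validity filter without dominating the
    # per-sample intensity totals that column normalization divides by.
    baseline = rng_base.normal(spec.base_mu, spec.base_sigma, spec.n_proteins)
    if spec.n_differential:
        baseline[: spec.n_differential] = rng_base.normal(
            spec.base_mu + spec.base_sigma,
            spec.base_sigma / 4.0,
            spec.n_differential,
        )

    shift = np.zeros((spec.n_proteins, n_samples))
    for i, eff in enumerate(effects):
        shift[i, labels == eff.group] = eff.effect_log2

    latent = (
        baseline[:, None]
        + shift
        + rng_noise.normal(0.0, spec.noise_sd, (spec.n_proteins, n_samples))
    )

    if np.isneginf(spec.missing_mid):
        detected = np.ones_like(latent, dtype=bool)
    else:
        p_detect = expit(spec.missing_slope * (latent - spec.missing_mid))
        detected = rng_detect.random(latent.shape) < p_detect

    observed = np.where(detected, np.exp2(latent), np.nan)
    values = pd.DataFrame(observed, index=ids, columns=list(design.samples))
    matrix = ProteinMatrix(values=values, flags=empty_flags(ids), design=design,
                           log2_scale=False)

    true_means = pd.DataFrame(
        {g: baseline[: spec.n_differential] for g in GROUP_LABELS},
        index=pd.Index(planted_ids, name="Protein IDs"),
    )
    for pid, eff in zip(planted_ids, effects):
        true_means.loc[pid, eff.group] += eff.effect_log2

    truth = GroundTruth(
        planted_ids=planted_ids,
        effects=dict(zip(planted_ids, effects)),
        true_group_means=true_means,
        directions=_directions(true_means),
        latent_log2=pd.DataFrame(latent, index=ids, columns=list(design.samples)),
        spec=spec,
    )
    return matrix, truth


def generate_qpcr_dataset(
    n_per_group: dict[str, int],
    true_fold_changes: dict[str, float],
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    control_group: str = "N",
    mean_target_ct: float = 25.0,
    mean_reference_ct: float = 20.0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table (two technical replicates, one reference gene).

    Each sample's target ΔCt is shifted by -log2(fold change of its group)
    relative to the control group, so the noiseless 2^-ΔΔCt computation
    recovers ``true_fold_changes`` exactly.  Technical replicate noise of sd
    ``ct_noise_sd`` is added independently to every Ct reading.
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be non-negative")
    for g, fc in true_fold_changes.items():
        if fc <= 0:
            raise ValueError(f"fold change for group {g!r} must be positive, got {fc}")
    if control_group not in n_per_group:
        raise ValueError(f"control group {control_group!r} not among groups")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for g in sorted(n_per_group):
        fc = true_fold_changes.get(g, 1.0)
        # ΔΔCt = -log2(fc): lower target Ct means higher expression
        dct_shift = -np.log2(fc) if g != control_group else 0.0
        for i in range(int(n_per_group[g])):
            ref = mean_reference_ct
            tgt = mean_target_ct + dct_shift
            rows.append({
                "sample_id": f"{g}{i+1:02d}",
                "group": g,
                "ct_rep1": tgt + rng.normal(0, ct_noise_sd),
                "ct_rep2": tgt + rng.normal(0, ct_noise_sd),
                "ref_rep1": ref + rng.normal(0, ct_noise_sd),
                "ref_rep2": ref + rng.normal(0, ct_noise_sd),
            })
    return pd.DataFrame(rows)
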