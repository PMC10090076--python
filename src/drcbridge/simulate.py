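"""Synthetic multi-study combination-screening generator.

Emulates the statistical structure that cross-study transfer depends on:
a shared pharmacology (each drug–cell-line pair has one underlying Hill
curve, wherever it is measured), heterogeneous dose designs between
studies (2–10 doses over study-specific ranges), replicate measurement
noise, and six combination-response labels in which overall sensitivity
carries a higher signal-to-noise ratio than the synergy scores.

Because the same drug–cell-line pair measured in two studies lies on one
Hill function, design-dependent encodings of its curve differ across
studies while design-independent (interpolated) encodings converge as
noise shrinks — the premise the prediction pipeline is built on.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .data_model import (
    SCORE_NAMES,
    CombinationRecord,
    DoseResponseCurve,
    ExpressionTable,
    StudyDataset,
    summarize_curve,
)

logger = logging.getLogger(__name__)

SYNERGY_SCORES = ("S", "Bliss", "HSA", "Loewe", "ZIP")


def packaged_smiles() -> list[str]:
    text = resources.files("drcbridge.data").joinpath("smiles.txt").read_text()
    return [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]


@dataclass(frozen=True)
class StudyDesign:
    """One study's screening design."""

    study_id: str
    n_doses: int = 5
    dose_min: float = 0.01  # µM
    dose_max: float = 10.0  # µM
    n_combinations: int = 1500
    replicate_count: int = 1

    def __post_init__(self) -> None:
        if not 2 <= self.n_doses <= 10:
            raise ValueError("dose count must be in [2, 10]")
        if not 0 < self.dose_min < self.dose_max:
            raise ValueError("need 0 < dose_min < dose_max")

    @property
    def dose_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.dose_min), np.log10(self.dose_max),
                           self.n_doses)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Pharmacology priors are drawn once per drug / cell line / pair:
    maximal inhibition Emax ~ U(30, 100)%, log10 EC50 ~ U(−2, 1) (0.01–10
    µM), Hill slope ~ U(0.5, 3). Measured responses get Gaussian noise of
    ``response_noise_sd`` % inhibition. Sensitivity (CSS-like) labels are
    a monotone function of both drugs' true relative inhibition plus a
    synergy contribution; the five synergy labels are the latent synergy
    plus heavier independent noise, so synergy is less replicable than
    sensitivity, as observed in real screens.
    """

    # the two default studies differ in dose count AND dose range, the two
    # axes of design heterogeneity seen across real screening studies
    studies: tuple[StudyDesign, ...] = (
        StudyDesign(study_id="STUDY_A", n_doses=5, dose_min=0.01, dose_max=10.0),
        StudyDesign(study_id="STUDY_B", n_doses=3, dose_min=0.03, dose_max=3.0),
    )
    n_drugs: int = 30  # per study
    n_cell_lines: int = 15  # per study
    drug_overlap: float = 0.2
    cell_line_overlap: float = 0.5
    emax_range: tuple[float, float] = (30.0, 100.0)
    ec50_log10_range: tuple[float, float] = (-2.0, 1.0)
    slope_range: tuple[float, float] = (0.5, 3.0)
    response_noise_sd: float = 5.0  # % inhibition
    synergy_sd: float = 10.0  # latent synergy spread (score units)
    sensitivity_noise_sd: float = 3.0  # CSS replicate noise
    synergy_noise_sd: float = 8.0  # synergy-score replicate noise
    synergy_weight: float = 0.5  # synergy contribution to sensitivity
    # study-level batch effects: one draw per (treatment-cell key, study),
    # shared by that study's replicates but independent between studies, so
    # inter-study replicability sits below intra-study replicability
    study_effect_sd_sensitivity: float = 2.0
    study_effect_sd_synergy: float = 5.0
    # per-study assay calibration: measured inhibition is
    # gain × true + offset (+ noise), with one gain/offset draw per study;
    # laboratories never read out % inhibition on exactly the same scale
    response_gain_sd: float = 0.1
    response_offset_sd: float = 3.0
    n_genes: int = 273
    n_factors: int = 3
    expression_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.drug_overlap <= 1 or not 0 <= self.cell_line_overlap <= 1:
            raise ValueError("overlap fractions must lie in [0, 1]")
        if not self.studies:
            raise ValueError("at least one study design required")


@dataclass
class GroundTruth:
    """Latent quantities behind a simulated dataset."""

    hill_params: dict  # (drug, cell) -> (emax, log10_ec50, slope)
    true_ri: dict  # (drug, cell) -> float
    latent_synergy: dict  # (frozenset{a,b}, cell) -> float
    noiseless_labels: dict  # (frozenset{a,b}, cell) -> {score: value}
    study_members: dict = field(default_factory=dict)  # study -> (drugs, cells)


@dataclass
class SimResult:
    studies: list[StudyDataset]
    expression: ExpressionTable
    truth: GroundTruth
    config: SimConfig


def hill_response(dose, emax: float, log10_ec50: float, slope: float):
    """% inhibition of a standard Hill curve at the given dose(s) in µM."""
    dose = np.asarray(dose, dtype=float)
    return emax / (1.0 + 10.0 ** (slope * (log10_ec50 - np.log10(dose))))


def true_relative_inhibition(emax, log10_ec50, slope,
                             lo: float = 0.01, hi: float = 10.0,
                             n: int = 201) -> float:
    """Design-independent RI: mean Hill inhibition over a reference
    log10-dose range, rescaled by 100."""
    grid = np.logspace(np.log10(lo), np.log10(hi), n)
    return float(np.mean(hill_response(grid, emax, log10_ec50, slope)) / 100.0)


def _member_ids(prefix, n_shared, n_per_study, n_studies):
    """Shared ids appear in every study; the rest are study-exclusive."""
    shared = [f"{prefix}_S{i:03d}" for i in range(n_shared)]
    members = []
    counter = itertools.count()
    for _ in range(n_studies):
        unique = [f"{prefix}_U{next(counter):03d}" for _ in range(n_per_study - n_shared)]
        members.append(shared + unique)
    all_ids = sorted(set(shared).union(*[set(m) for m in members]))
    return members, all_ids


def simulate(config: SimConfig) -> SimResult:
    """Generate the studies, the expression table and the ground truth.

    Deterministic given ``config.seed``. Every emitted record maps to
    exactly one ground-truth entry; replicates of a treatment–cell-line
    key share its latent labels and differ only in measurement noise.
    """
    rng = np.random.default_rng(config.seed)
    n_studies = len(config.studies)

    n_shared_drugs = int(round(config.drug_overlap * config.n_drugs))
    n_shared_cells = int(round(config.cell_line_overlap * config.n_cell_lines))
    study_drugs, all_drugs = _member_ids("DRUG", n_shared_drugs,
                                         config.n_drugs, n_studies)
    study_cells, all_cells = _member_ids("CELL", n_shared_cells,
                                         config.n_cell_lines, n_studies)

    smiles_pool = packaged_smiles()
    if len(all_drugs) > len(smiles_pool):
        logger.warning("more drugs (%d) than packaged SMILES (%d); recycling",
                       len(all_drugs), len(smiles_pool))
    smiles_of = {d: smiles_pool[i % len(smiles_pool)]
                 for i, d in enumerate(all_drugs)}

    # cell-line latent factors drive both expression and drug sensitivity
    factors = {c: rng.normal(size=config.n_factors) for c in all_cells}
    loadings = rng.normal(size=(config.n_genes, config.n_factors))
    expr = {
        c: loadings @ factors[c]
        + config.expression_noise_sd * rng.normal(size=config.n_genes)
        for c in all_cells
    }
    gene_ids = [f"GENE{i:04d}" for i in range(config.n_genes)]
    expression = ExpressionTable(
        values=pd.DataFrame({c: expr[c] for c in all_cells}, index=gene_ids)
    )

    # per-drug pharmacology, shifted per cell line through the first factor
    drug_emax = {d: rng.uniform(*config.emax_range) for d in all_drugs}
    drug_ec50 = {d: rng.uniform(*config.ec50_log10_range) for d in all_drugs}
    drug_slope = {d: rng.uniform(*config.slope_range) for d in all_drugs}

    hill_params: dict = {}
    true_ri: dict = {}

    def pair_params(drug: str, cell: str):
        if (drug, cell) not in hill_params:
            shift = 0.3 * factors[cell][0] + 0.1 * rng.normal()
            emax = float(np.clip(drug_emax[drug] * (1.0 + 0.1 * factors[cell][1]),
                                 5.0, 100.0))
            params = (emax, drug_ec50[drug] + shift, drug_slope[drug])
            hill_params[(drug, cell)] = params
            true_ri[(drug, cell)] = true_relative_inhibition(*params)
        return hill_params[(drug, cell)]

    latent_synergy: dict = {}
    noiseless: dict = {}
    study_effects: dict = {}  # (key, study_id) -> {score: offset}

    def combo_truth(drug_a: str, drug_b: str, cell: str):
        key = (frozenset((drug_a, drug_b)), cell)
        if key not in latent_synergy:
            pair_params(drug_a, cell)
            pair_params(drug_b, cell)
            syn = rng.normal(scale=config.synergy_sd)
            latent_synergy[key] = syn
            css = (
                50.0 * (true_ri[(drug_a, cell)] + true_ri[(drug_b, cell)])
                + config.synergy_weight * syn
            )
            labels = {"CSS": css}
            for score in SYNERGY_SCORES:
                labels[score] = syn
            noiseless[key] = labels
        return key

    def study_effect(key, study_id):
        if (key, study_id) not in study_effects:
            effects = {"CSS": rng.normal(scale=config.study_effect_sd_sensitivity)}
            for score in SYNERGY_SCORES:
                effects[score] = rng.normal(scale=config.study_effect_sd_synergy)
            study_effects[(key, study_id)] = effects
        return study_effects[(key, study_id)]

    studies = []
    for s, design in enumerate(config.studies):
        drugs, cells = study_drugs[s], study_cells[s]
        gain = 1.0 + rng.normal(scale=config.response_gain_sd)
        offset = rng.normal(scale=config.response_offset_sd)
        available = [(a, b, c)
                     for a, b in itertools.combinations(sorted(drugs), 2)
                     for c in sorted(cells)]
        if design.n_combinations > len(available):
            raise ValueError(
                f"{design.study_id}: {design.n_combinations} combinations "
                f"requested but only {len(available)} pair-cell keys available"
            )
        chosen_idx = rng.choice(len(available), size=design.n_combinations,
                                replace=False)
        records = []
        for idx in chosen_idx:
            drug_a, drug_b, cell = available[idx]
            key = combo_truth(drug_a, drug_b, cell)
            for rep in range(design.replicate_count):
                curves = {}
                for drug in (drug_a, drug_b):
                    emax, lec50, slope = pair_params(drug, cell)
                    clean = hill_response(design.dose_grid, emax, lec50, slope)
                    noisy = gain * clean + offset + rng.normal(
                        scale=config.response_noise_sd, size=clean.shape)
                    curves[drug] = DoseResponseCurve(
                        drug_id=drug, cell_line_id=cell,
                        study_id=design.study_id,
                        doses=tuple(design.dose_grid),
                        responses=tuple(noisy),
                        replicate_id=rep,
                    )
                batch = study_effect(key, design.study_id)
                labels = {}
                labels["CSS"] = noiseless[key]["CSS"] + batch["CSS"] + rng.normal(
                    scale=config.sensitivity_noise_sd)
                for score in SYNERGY_SCORES:
                    labels[score] = noiseless[key][score] + batch[score] + rng.normal(
                        scale=config.synergy_noise_sd)
                records.append(CombinationRecord(
                    drug_a_id=drug_a, drug_b_id=drug_b,
                    smiles_a=smiles_of[drug_a], smiles_b=smiles_of[drug_b],
                    cell_line_id=cell, study_id=design.study_id,
                    labels=labels,
                    curve_a=curves[drug_a], curve_b=curves[drug_b],
                    summary_a=summarize_curve(curves[drug_a]),
                    summary_b=summarize_curve(curves[drug_b]),
                    replicate_id=rep,
                ))
        studies.append(StudyDataset(study_id=design.study_id, combinations=records))

    truth = GroundTruth(
        hill_params=hill_params,
        true_ri=true_ri,
        latent_synergy=latent_synergy,
        noiseless_labels=noiseless,
        study_members={d.study_id: (study_drugs[i], study_cells[i])
                       for i, d in enumerate(config.studies)},
    )
    return SimResult(studies=studies, expression=expression, truth=truth,
                     config=config)


def attenuation_oracle(config: SimConfig, score: str,
                       signal_var: float | None = None) -> float:
    """Closed-form expected Pearson r between intra-study replicate labels.

    Replicates within one study share the latent (noiseless) label and
    that study's batch offset, and carry independent measurement noise,
    so their correlation is var(signal) / (var(signal) + var(noise)) with
    signal = latent + batch. For the synergy scores the signal variance
    follows from the config; for sensitivity (or any score) an explicit
    latent ``signal_var`` — e.g. the variance of ground-truth noiseless
    labels — may be supplied, to which the batch variance is added.
    """
    if score == "CSS":
        noise_var = config.sensitivity_noise_sd ** 2
        if signal_var is None:
            raise ValueError(
                "CSS latent variance depends on the RI distribution; pass "
                "signal_var computed from the ground truth"
            )
        signal_var = signal_var + config.study_effect_sd_sensitivity ** 2
    elif score in SYNERGY_SCORES:
        noise_var = config.synergy_noise_sd ** 2
        if signal_var is None:
            signal_var = config.synergy_sd ** 2
        signal_var = signal_var + config.study_effect_sd_synergy ** 2
    else:
        raise ValueError(f"unknown score {score!r}")
    return signal_var / (signal_var + noise_var)
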