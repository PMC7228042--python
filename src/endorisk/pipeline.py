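"""The endometrial-cancer risk model layer.

Binds the generic Bayesian-network machinery to the clinical problem:
the 14 network variables with their preoperative encodings, a documented
(reconstructed, config-overridable) default topology, single-patient
prediction of lymph-node metastasis (LNM) and 5-year disease-specific
survival (DSS), the end-to-end develop/validate workflow, and the
marker-block sensitivity analyses.

Variable encodings follow the standard preoperative cutoffs: Ca-125
dichotomized at 35 IU/ml, thrombocyte count at 400e9/l, ER/PR/L1CAM
immunohistochemistry at 10% stained tumor cells, p53 as wild type vs
aberrant, tumor grade 1/2/3, lymphadenopathy on imaging yes/no, cervical
cytology normal/abnormal.  Values exactly at a cutoff go to the ">=" level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn import (
    MISSING,
    BayesianNetwork,
    CategoricalVariable,
    NetworkError,
    NetworkStructure,
    encode_table,
    validate_network,
)
from .inference import posterior_marginals
from .imputation import impute_dataset
from .learning import (
    ArcConstraintSet,
    ArcStrengthTable,
    bootstrap_arc_strengths,
    fit_cpts,
    threshold_arcs,
)
from .validation import (
    ScoredOutcomes,
    auc,
    brier,
    calibration_table,
    cutoff_metrics,
    decision_curve,
    predicted_observed_ratio,
    risk_group_table,
)

__all__ = [
    "VARIABLES",
    "PREDICTORS",
    "INTERMEDIATE",
    "OUTCOMES",
    "MOLECULAR_BLOCK",
    "CLINICAL_BLOCK",
    "PatientRecord",
    "EndoriskSpec",
    "encode_patient",
    "default_structure",
    "predict_patient",
    "predict_cohort",
    "validation_report",
    "develop_network",
    "sensitivity_analysis",
    "DevelopConfig",
]

# -- the 14 variables ------------------------------------------------------------

VARIABLES: tuple[CategoricalVariable, ...] = (
    CategoricalVariable("preop_grade", ("1", "2", "3")),
    CategoricalVariable("ER", ("positive", "negative")),
    CategoricalVariable("PR", ("positive", "negative")),
    CategoricalVariable("p53", ("wildtype", "aberrant")),
    CategoricalVariable("L1CAM", ("negative", "positive")),
    CategoricalVariable("CA125", ("<35", ">=35")),
    CategoricalVariable("thrombocytes", ("<400", ">=400")),
    CategoricalVariable("lymphadenopathy", ("no", "yes")),
    CategoricalVariable("cytology", ("normal", "abnormal")),
    CategoricalVariable("postop_grade", ("1", "2", "3")),
    CategoricalVariable("MI", ("<50", ">=50")),
    CategoricalVariable("LVSI", ("no", "yes")),
    CategoricalVariable("LNM", ("negative", "positive")),
    CategoricalVariable("DSS5", ("survived", "died")),
)

PREDICTORS = (
    "preop_grade",
    "ER",
    "PR",
    "p53",
    "L1CAM",
    "CA125",
    "thrombocytes",
    "lymphadenopathy",
    "cytology",
)
INTERMEDIATE = ("postop_grade", "MI", "LVSI")
OUTCOMES = ("LNM", "DSS5")

MOLECULAR_BLOCK = ("ER", "PR", "p53", "L1CAM")
CLINICAL_BLOCK = ("CA125", "thrombocytes", "lymphadenopathy", "cytology")

#: outcome level counted as the event
EVENT_LEVEL = {"LNM": "positive", "DSS5": "died"}


# -- patient records and encoding --------------------------------------------------


@dataclass
class PatientRecord:
    """Raw preoperative findings; any field may be None (absent)."""

    age: float | None = None  # years; recorded but not a network node
    ca125: float | None = None  # IU/ml
    thrombocytes: float | None = None  # 1e9 cells / l
    er_percent: float | None = None  # % tumor cells with nuclear staining
    pr_percent: float | None = None
    l1cam_percent: float | None = None  # % cells with membranous staining
    p53: str | None = None  # "wildtype" | "aberrant"
    preop_grade: int | str | None = None  # 1 | 2 | 3
    lymphadenopathy: str | None = None  # "no" | "yes"
    cytology: str | None = None  # "normal" | "abnormal"

    def __post_init__(self) -> None:
        for name in ("ca125", "thrombocytes", "er_percent", "pr_percent", "l1cam_percent"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise NetworkError(f"{name} must be nonnegative, got {v}")


def _dichotomize(value: float, cutoff: float, low: str, high: str) -> str:
    # boundary values map to the ">=" level
    return high if value >= cutoff else low


def encode_patient(record: PatientRecord | Mapping[str, object]) -> dict[str, str]:
    """Translate raw findings into network evidence; absent fields are omitted."""
    if not isinstance(record, PatientRecord):
        record = PatientRecord(**dict(record))
    evidence: dict[str, str] = {}
    if record.preop_grade is not None:
        grade = str(record.preop_grade)
        if grade not in ("1", "2", "3"):
            raise NetworkError(f"preoperative grade must be 1, 2 or 3, got {grade!r}")
        evidence["preop_grade"] = grade
    if record.er_percent is not None:
        evidence["ER"] = _dichotomize(record.er_percent, 10.0, "negative", "positive")
    if record.pr_percent is not None:
        evidence["PR"] = _dichotomize(record.pr_percent, 10.0, "negative", "positive")
    if record.l1cam_percent is not None:
        evidence["L1CAM"] = _dichotomize(record.l1cam_percent, 10.0, "negative", "positive")
    if record.p53 is not None:
        if record.p53 not in ("wildtype", "aberrant"):
            raise NetworkError(f"p53 must be 'wildtype' or 'aberrant', got {record.p53!r}")
        evidence["p53"] = record.p53
    if record.ca125 is not None:
        evidence["CA125"] = _dichotomize(record.ca125, 35.0, "<35", ">=35")
    if record.thrombocytes is not None:
        evidence["thrombocytes"] = _dichotomize(record.thrombocytes, 400.0, "<400", ">=400")
    if record.lymphadenopathy is not None:
        if record.lymphadenopathy not in ("no", "yes"):
            raise NetworkError(f"lymphadenopathy must be 'no'/'yes', got {record.lymphadenopathy!r}")
        evidence["lymphadenopathy"] = record.lymphadenopathy
    if record.cytology is not None:
        if record.cytology not in ("normal", "abnormal"):
            raise NetworkError(f"cytology must be 'normal'/'abnormal', got {record.cytology!r}")
        evidence["cytology"] = record.cytology
    return evidence


# -- network specification ---------------------------------------------------------


@dataclass
class EndoriskSpec:
    """The 14-variable network skeleton with role annotations.

    The default arc set beyond the text-attested causal arcs
    (MI -> LNM, LVSI -> LNM, LNM -> DSS5) is an explicit reconstruction and
    can be overridden via configuration; analyses must not rely on the
    reconstructed arcs being the published ones.
    """

    variables: tuple[CategoricalVariable, ...] = VARIABLES
    arcs: frozenset[tuple[str, str]] = frozenset()
    provenance: str = "reconstructed — edit via config"

    def structure(self) -> NetworkStructure:
        return NetworkStructure(self.variables, self.arcs)

    def __post_init__(self) -> None:
        s = self.structure()  # raises on cycles / undeclared endpoints
        # the terminal outcome never has children
        if s.children("DSS5"):
            raise NetworkError("DSS5 must be a terminal (childless) node")


#: arcs directly attested by the causal reading of the model
ATTESTED_ARCS = frozenset(
    {("MI", "LNM"), ("LVSI", "LNM"), ("LNM", "DSS5")}
)

#: the documented default reconstruction of the remaining topology:
#: tumor biology (postoperative grade) drives the biopsy markers and local
#: invasion; nodal disease drives the diagnostic findings; survival depends
#: on nodal status and p53 class.
DEFAULT_ARCS = ATTESTED_ARCS | frozenset(
    {
        ("postop_grade", "preop_grade"),
        ("postop_grade", "ER"),
        ("postop_grade", "PR"),
        ("postop_grade", "p53"),
        ("postop_grade", "L1CAM"),
        ("postop_grade", "MI"),
        ("postop_grade", "LVSI"),
        ("LNM", "lymphadenopathy"),
        ("LNM", "thrombocytes"),
        ("LNM", "CA125"),
        ("LVSI", "cytology"),
        ("p53", "DSS5"),
    }
)


def default_structure() -> EndoriskSpec:
    """The default 14-node topology (attested arcs plus the reconstruction)."""
    return EndoriskSpec(arcs=DEFAULT_ARCS)


# -- prediction --------------------------------------------------------------------


def _check_evidence_roles(evidence: Mapping[str, str]) -> None:
    forbidden = set(evidence) & (set(INTERMEDIATE) | set(OUTCOMES))
    if forbidden:
        raise NetworkError(
            f"intermediate/outcome nodes cannot be supplied as evidence: {sorted(forbidden)}"
        )


def predict_patient(
    bn: BayesianNetwork, record: PatientRecord | Mapping[str, object]
) -> dict:
    """Posterior risk profile for one patient.

    Encodes the raw record, propagates it as evidence, and returns the
    posterior marginals of the outcomes and intermediate nodes, plus the
    two headline probabilities.  Intermediate and outcome nodes are never
    accepted as evidence.
    """
    if isinstance(record, (PatientRecord,)):
        evidence = encode_patient(record)
    elif isinstance(record, Mapping) and set(record) <= {
        f for f in PatientRecord.__dataclass_fields__
    }:
        evidence = encode_patient(record)
    else:
        evidence = {str(k): str(v) for k, v in dict(record).items()}
    _check_evidence_roles(evidence)
    targets = list(OUTCOMES) + list(INTERMEDIATE)
    marg = posterior_marginals(bn, evidence, targets)
    out = {"evidence": evidence, "marginals": {}}
    for name in targets:
        levels = bn.variable(name).levels
        out["marginals"][name] = {
            lvl: float(p) for lvl, p in zip(levels, marg[name])
        }
    lnm_levels = bn.variable("LNM").levels
    dss_levels = bn.variable("DSS5").levels
    out["lnm_risk"] = float(marg["LNM"][lnm_levels.index(EVENT_LEVEL["LNM"])])
    out["dss5_survival"] = 1.0 - float(
        marg["DSS5"][dss_levels.index(EVENT_LEVEL["DSS5"])]
    )
    return out


def predict_cohort(
    bn: BayesianNetwork,
    data: pd.DataFrame,
    outcome: str = "LNM",
    evidence_vars: Sequence[str] = PREDICTORS,
) -> np.ndarray:
    """Per-row P(outcome event | observed predictor cells).

    Rows use whatever predictor cells they have — no imputation is applied
    at validation time; missing findings simply contribute no evidence.
    Identical evidence patterns share one inference call.
    """
    if outcome not in OUTCOMES:
        raise NetworkError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    structure = bn.structure
    evidence_vars = [v for v in evidence_vars if v in structure.names]
    codes = encode_table(data[list(evidence_vars)].assign(
        **{n: MISSING for n in structure.names if n not in evidence_vars}
    ), structure)
    col = {n: j for j, n in enumerate(structure.names)}
    ev_cols = [col[v] for v in evidence_vars]
    event_idx = structure.variable(outcome).index_of(EVENT_LEVEL[outcome])
    cache: dict[tuple, float] = {}
    out = np.empty(len(data))
    for i in range(len(data)):
        key = tuple(codes[i, j] for j in ev_cols)
        p = cache.get(key)
        if p is None:
            evidence = {
                v: structure.variable(v).levels[codes[i, col[v]]]
                for v in evidence_vars
                if codes[i, col[v]] >= 0
            }
            marg = posterior_marginals(bn, evidence, [outcome])
            p = float(marg[outcome][event_idx])
            cache[key] = p
        out[i] = p
    return out


# -- validation battery ------------------------------------------------------------


def validation_report(
    bn: BayesianNetwork,
    data: pd.DataFrame,
    outcome: str = "LNM",
    cutoffs: Sequence[float] = (0.01, 0.05, 0.15, 0.25),
    n_bins: int = 10,
    decision_grid: Sequence[float] | None = None,
    evidence_vars: Sequence[str] = PREDICTORS,
    seed: int = 0,
) -> tuple[dict, ScoredOutcomes]:
    """Full evaluation of the model on a cohort with observed outcomes.

    Rows whose outcome is missing are dropped (with a note in the report);
    predictions use each row's available predictor evidence only.
    """
    structure = bn.structure
    outcome_col = data[outcome].astype(object)
    known = np.array(
        [v is not None and v == v and v not in ("", MISSING) for v in outcome_col]
    )
    used = data.loc[known].reset_index(drop=True)
    event = EVENT_LEVEL[outcome]
    y = (used[outcome].astype(str) == event).to_numpy().astype(int)
    probs = predict_cohort(bn, used, outcome=outcome, evidence_vars=evidence_vars)
    scored = ScoredOutcomes(probs, y)
    if decision_grid is None:
        decision_grid = np.arange(0.01, 0.60, 0.01)
    report = {
        "outcome": outcome,
        "n": int(len(scored)),
        "n_dropped_missing_outcome": int((~known).sum()),
        "prevalence": scored.prevalence,
        "auc": auc(scored),
        "brier": brier(scored),
        "calibration": calibration_table(scored, n_bins=n_bins).to_dict(orient="records"),
        "predicted_observed": predicted_observed_ratio(scored, seed=seed),
        "cutoffs": [cutoff_metrics(scored, c) for c in cutoffs],
        "risk_groups": risk_group_table(scored).to_frame().to_dict(orient="records"),
        "decision_curve": decision_curve(scored, decision_grid).to_frame().to_dict(
            orient="list"
        ),
    }
    return report, scored


# -- development workflow ----------------------------------------------------------


@dataclass
class DevelopConfig:
    """Settings for the develop-network workflow; all seeds recorded."""

    algorithm: str = "hill_climb"  # or "tabu"
    score_type: str = "bic"
    n_bootstrap: int = 500
    threshold: float = 0.7
    bootstrap_seed: int = 0
    ess: float = 1.0
    imputation_samples: int = 500
    imputation_seed: int = 0
    tabu_len: int = 10

    @classmethod
    def from_dict(cls, payload: Mapping) -> "DevelopConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in dict(payload).items() if k in known})


def develop_network(
    data: pd.DataFrame,
    constraints: ArcConstraintSet = ArcConstraintSet(),
    config: DevelopConfig | None = None,
    variables: Sequence[CategoricalVariable] = VARIABLES,
) -> tuple[BayesianNetwork, ArcStrengthTable, dict]:
    """End-to-end model development.

    Stages: bootstrap structure learning on complete cases, arc-strength
    thresholding merged with the expert whitelist, an initial fit on
    complete cases, model-based imputation of the full cohort, a final CPT
    fit on the completed data, and a goodness-of-fit report comparing the
    final model against the whitelist-only topology.
    """
    config = config or DevelopConfig()
    names = [v.name for v in variables]
    missing_mask = data[names].isin([MISSING, ""]) | data[names].isna()
    complete = data.loc[~missing_mask.any(axis=1), names].reset_index(drop=True)
    if len(complete) < 10:
        raise NetworkError(
            f"only {len(complete)} complete cases; too few for structure learning"
        )
    strengths = bootstrap_arc_strengths(
        complete,
        variables,
        constraints,
        algorithm=config.algorithm,
        n_bootstrap=config.n_bootstrap,
        seed=config.bootstrap_seed,
        score_type=config.score_type,
        tabu_len=config.tabu_len,
    )
    learned = threshold_arcs(strengths, config.threshold)
    arcs = set(constraints.whitelist)
    for arc in sorted(learned, key=lambda a: -strengths.strength(*a)):
        if arc in arcs or (arc[1], arc[0]) in arcs:
            continue
        if arc in constraints.blacklist:
            continue
        try:
            NetworkStructure(variables, arcs | {arc})
        except NetworkError:
            continue  # would conflict with whitelist orientation
        arcs.add(arc)
    structure = NetworkStructure(variables, arcs)
    initial = fit_cpts(structure, complete, ess=max(config.ess, 1.0))
    imputed = impute_dataset(
        initial,
        data[names],
        n_samples=config.imputation_samples,
        seed=config.imputation_seed,
    )
    final = fit_cpts(structure, imputed.completed[names], ess=config.ess)
    arc_metadata = {
        arc: {
            "strength": strengths.strength(*arc),
            "direction_agreement": strengths.direction_agreement(*arc),
            "provenance": "expert" if arc in constraints.whitelist else "learned",
        }
        for arc in sorted(arcs)
    }
    final.arc_metadata = arc_metadata
    whitelist_only = fit_cpts(
        NetworkStructure(variables, constraints.whitelist),
        imputed.completed[names],
        ess=max(config.ess, 1.0),
    )
    from .bn import log_likelihood

    report = {
        "n": int(len(data)),
        "n_complete_cases": int(len(complete)),
        "n_imputed_cells": imputed.n_imputed,
        "imputed_counts": imputed.imputed_counts(),
        "arcs": sorted(arcs),
        "log_likelihood_final": log_likelihood(final, imputed.completed[names]),
        "log_likelihood_whitelist_only": log_likelihood(
            whitelist_only, imputed.completed[names]
        ),
        "seeds": {
            "bootstrap": config.bootstrap_seed,
            "imputation": config.imputation_seed,
        },
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
    }
    return final, strengths, report


# -- sensitivity analyses ----------------------------------------------------------


def sensitivity_analysis(
    bn: BayesianNetwork,
    data: pd.DataFrame,
    marker_block: str,
    outcome: str = "LNM",
    seed: int = 0,
) -> dict:
    """Re-validate with one predictor block withheld from the evidence.

    ``marker_block`` names the block to omit: "molecular" (ER, PR, p53,
    L1CAM) or "clinical" (Ca-125, thrombocytes, lymphadenopathy, cytology);
    preoperative grade stays in either case.  Reports the restricted metrics
    and their deltas against the full-evidence run.
    """
    blocks = {"molecular": MOLECULAR_BLOCK, "clinical": CLINICAL_BLOCK}
    if marker_block not in blocks:
        raise NetworkError(f"marker_block must be one of {sorted(blocks)}")
    omitted = blocks[marker_block]
    restricted_vars = [v for v in PREDICTORS if v not in omitted]
    full, _ = validation_report(bn, data, outcome=outcome, seed=seed)
    restricted, _ = validation_report(
        bn, data, outcome=outcome, evidence_vars=restricted_vars, seed=seed
    )
    return {
        "omitted_block": marker_block,
        "omitted_variables": list(omitted),
        "full": full,
        "restricted": restricted,
        "delta_auc": restricted["auc"]["auc"] - full["auc"]["auc"],
        "delta_brier": restricted["brier"] - full["brier"],
    }
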