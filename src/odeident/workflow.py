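"""End-to-end analysis workflow: SIA -> fit -> PIA, with structured reports.

The model-development loop runs structural identifiability first (both
the Taylor-series and the Jacobian-rank method), because a structurally
unidentifiable model cannot be practically identifiable: in that case the
workflow stops before any fitting and reports which parameters would need
to be known a priori.  Otherwise it fits the data by weighted least
squares and profiles every parameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

from . import __version__
from .fitting import fit as fit_op
from .model import Dataset, OdeModel, parameter_point
from .profiling import profile_all
from .rank import rank_test, suggest_known
from .synthetic import Design, generate
from .taylor import analyze_taylor

__all__ = ["AnalysisReport", "run_workflow", "WorkflowOptions"]

SCHEMA_VERSION = 1

STATUS_OK = "identifiable"
STATUS_STRUCTURAL = "structurally-unidentifiable"
STATUS_PRACTICAL = "practically-unidentifiable"


@dataclass
class WorkflowOptions:
    alpha: float = 0.05
    df_convention: str = "pointwise"
    seed: int = 1
    n_starts: int = 5
    taylor_timeout: Optional[float] = 60.0
    rank_trials: int = 3
    force: bool = False  # continue to PIA even if structurally unidentifiable
    init: Optional[Mapping] = None
    bounds: Optional[Mapping] = None
    profile_params: Optional[list] = None


@dataclass
class AnalysisReport:
    """Structured record of a full identifiability workflow run."""

    model: dict
    sia: dict
    status: str
    fit: Optional[dict] = None
    pia: Optional[dict] = None
    provenance: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "model": self.model,
            "sia": self.sia,
            "status": self.status,
            "fit": self.fit,
            "pia": self.pia,
            "provenance": self.provenance,
        }

    def to_json(self, path=None, indent: int = 2):
        text = json.dumps(self.to_dict(), indent=indent, default=_json_default)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    @property
    def exit_code(self) -> int:
        return {STATUS_OK: 0, STATUS_STRUCTURAL: 3, STATUS_PRACTICAL: 4}[self.status]


def _json_default(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    return str(obj)


def run_workflow(
    model: OdeModel,
    data: Optional[Dataset] = None,
    design: Optional[Design] = None,
    design_params: Optional[Mapping] = None,
    options: Optional[WorkflowOptions] = None,
) -> AnalysisReport:
    """Run SIA (both methods), then — if structurally identifiable — fit
    and profile.

    Supply either a dataset or a synthetic design plus generating
    parameters.  When structural analysis finds a deficiency the report
    stops there (status ``structurally-unidentifiable``) with minimal
    known-parameter suggestions, unless ``options.force``.
    """
    opt = options or WorkflowOptions()

    model_summary = {
        "name": model.name,
        "n_states": model.n_states,
        "n_params": model.n_params,
        "n_outputs": model.n_outputs,
        "states": [str(s) for s in model.states],
        "parameters": [str(p) for p in model.params],
        "outputs": list(model.output_names),
        "config_hash": model.config_hash(),
    }
    provenance = {
        "package": "odeident",
        "version": __version__,
        "seed": opt.seed,
        "alpha": opt.alpha,
        "df_convention": opt.df_convention,
        "taylor_timeout_s": opt.taylor_timeout,
        "rank_trials": opt.rank_trials,
    }

    taylor_verdict = analyze_taylor(model, timeout=opt.taylor_timeout)
    rank_result = rank_test(model, trials=opt.rank_trials, seed=opt.seed)
    sia = {"taylor": taylor_verdict.to_dict(), "rank": rank_result.to_dict()}

    structurally_ok = rank_result.identifiable and (
        taylor_verdict.status != "ok" or taylor_verdict.identifiable
    )
    if not structurally_ok:
        sia["suggested_known_sets"] = suggest_known(
            model, trials=opt.rank_trials, seed=opt.seed
        ).to_dict()
        if not opt.force:
            return AnalysisReport(
                model=model_summary,
                sia=sia,
                status=STATUS_STRUCTURAL,
                provenance=provenance,
            )

    if data is None:
        if design is None or design_params is None:
            raise ValueError(
                "supply a dataset, or a synthetic design with generating parameters"
            )
        data = generate(model, parameter_point(model, design_params), design, seed=opt.seed)
        provenance["synthetic_design"] = design.name or "custom"
    data.validate_against(model)

    init = opt.init
    if init is None:
        init = design_params if design_params is not None else {
            str(u): 1.0 for u in model.unknowns
        }
    fit_result = fit_op(
        model,
        data,
        init=init,
        bounds=opt.bounds,
        n_starts=opt.n_starts,
        seed=opt.seed,
    )
    fit_summary = {
        "estimate": fit_result.estimate,
        "objective": fit_result.objective,
        "converged": fit_result.success,
        "n_starts": fit_result.n_starts,
        "n_records": len(data),
    }

    profiles = profile_all(
        model,
        data,
        fit_result,
        params=opt.profile_params,
        alpha=opt.alpha,
        df_convention=opt.df_convention,
    )
    status = STATUS_OK if not profiles.unidentifiable_params else STATUS_PRACTICAL
    if not structurally_ok:
        status = STATUS_STRUCTURAL  # forced PIA never upgrades the verdict
    return AnalysisReport(
        model=model_summary,
        sia=sia,
        status=status,
        fit=fit_summary,
        pia=profiles.to_dict(),
        provenance=provenance,
    )
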