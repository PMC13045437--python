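"""End-to-end orchestration: featurize -> hierarchy -> latents -> symbolic
regression -> report, plus cross-validation, metrics and solvent
recommendation.

The discovered equations live in the standardized latent gauge; the affine
standardization transforms (shift, scale, sign per latent) are published in
the report so raw-gauge equations can be derived.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from . import symreg
from .equations import EquationChain, reference_chain
from .errors import ConfigError, SchemaError, ValidationError
from .features import (
    SOLVENT_NAMES, SOLVENT_SLICE, SoluteDescriptors, SolventComposition,
    TLCRecord, features_matrix, rf_vector,
)
from .modular_net import (
    HierarchyConfig, HierarchyResult, HyperParams, TrainedStage,
    run_hierarchy,
)
from .symreg import ParetoFront, SRConfig, select, to_canonical_string
from .synthetic import SynthDataset
from .util import clip_rf, logit, sigmoid

__all__ = [
    "Metrics", "compute_metrics", "PipelineConfig", "RunResult", "run_uhsr",
    "CVResult", "crossvalidate", "predict", "recommend_solvent",
    "EQUATION_KEYS", "REPORT_KEYS",
]

#: Required keys of each equation entry in a report.
EQUATION_KEYS = ("target", "variables", "expression", "complexity",
                 "train_loss", "r2", "rmse")
#: Required top-level report keys.
REPORT_KEYS = ("seed", "config_hash", "n_train", "n_test", "equations",
               "pareto", "latent_standardization", "metrics")


@dataclass(frozen=True)
class Metrics:
    """Coefficient of determination, root-mean-square error and the two
    correlation coefficients; r2 is None (flagged) for zero-variance
    targets."""

    r2: Optional[float]
    rmse: float
    pearson_r: Optional[float]
    spearman_rs: Optional[float]
    r2_undefined: bool = False

    def to_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "pearson_r": self.pearson_r,
                "spearman_rs": self.spearman_rs,
                "r2_undefined": self.r2_undefined}


def compute_metrics(y, y_hat) -> Metrics:
    """R2 = 1 - SSE/SST and RMSE = sqrt(SSE/N), plus Pearson r and
    Spearman r_s."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise SchemaError("y and y_hat must be equal-length vectors")
    if len(y) < 2:
        raise ValidationError("need at least 2 samples")
    sse = float(np.sum((y - y_hat) ** 2))
    rmse = float(np.sqrt(sse / len(y)))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return Metrics(r2=None, rmse=rmse, pearson_r=None, spearman_rs=None,
                       r2_undefined=True)
    r2 = 1.0 - sse / sst
    if np.std(y_hat) == 0.0:
        pearson = spearman = None
    else:
        pearson = float(np.corrcoef(y, y_hat)[0, 1])
        spearman = float(stats.spearmanr(y, y_hat).statistic)
    return Metrics(r2=r2, rmse=rmse, pearson_r=pearson, spearman_rs=spearman)


# ---------------------------------------------------------------------------
# The full pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one pipeline run.

    The SR primitive set defaults to {+, -, *}: the latent-level governing
    forms are polynomial, and the sigmoid link is handled by fitting the Rf
    target on the logit scale and reporting sigma(...) of the selected
    expression."""

    hp: HyperParams = field(default_factory=HyperParams)
    sr: SRConfig = field(default_factory=lambda: SRConfig(
        primitives=("add", "sub", "mul")))
    seed: int = 0
    test_fraction: float = 0.1
    canonicalize: bool = True
    sr_targets: tuple = ("rf", "psi", "xi", "beta")

    def config_hash(self) -> str:
        blob = json.dumps({
            "hp": self.hp.__dict__ if hasattr(self.hp, "__dict__")
            else str(self.hp),
            "sr": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(self.sr).items()},
            "seed": self.seed, "test_fraction": self.test_fraction,
            "canonicalize": self.canonicalize,
            "sr_targets": list(self.sr_targets),
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    report: dict                 # JSON-serializable
    hierarchy: HierarchyResult
    fronts: dict                 # target -> ParetoFront


def _records_of(dataset) -> list:
    if isinstance(dataset, SynthDataset):
        return dataset.records
    return list(dataset)


def _front_json(front: ParetoFront) -> list:
    return [{"complexity": m.complexity, "loss": m.loss,
             "expression": to_canonical_string(m.tree, precision=4)}
            for m in front]


def _standardization_json(stages: dict) -> dict:
    out = {}
    for key, stage in stages.items():
        out[key] = {
            name: {"shift": float(stage.shift[i]),
                   "scale": float(stage.scale[i]),
                   "sign": float(stage.sign[i])}
            for i, name in enumerate(stage.latent_names)
        }
    return out


def run_uhsr(dataset, config: Optional[PipelineConfig] = None,
             test_records: Optional[Sequence[TLCRecord]] = None) -> RunResult:
    """Run the three-stage hierarchy and symbolic regression on a dataset.

    Fits, per run: (i) logit(Rf) vs (psi, xi); (ii) psi vs the five solvent
    fractions; (iii) xi vs (alpha, beta); (iv) beta vs (gamma1..gamma5).
    Held-out metrics come from `test_records` if given, otherwise from an
    internal seeded split of `test_fraction`.
    """
    from threadpoolctl import threadpool_limits

    config = config or PipelineConfig()
    records = _records_of(dataset)
    if not records or records[0].rf is None:
        raise ValidationError("run_uhsr needs records with observed Rf")
    # single-threaded BLAS keeps the whole run bitwise reproducible
    with threadpool_limits(limits=1):
        return _run_uhsr_inner(records, config, test_records)


def _run_uhsr_inner(records, config, test_records):

    if test_records is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        perm = rng.permutation(len(records))
        n_test = max(1, int(round(len(records) * config.test_fraction)))
        test_records = [records[i] for i in perm[:n_test]]
        train_records = [records[i] for i in perm[n_test:]]
    else:
        train_records = records
        test_records = list(test_records)

    hier = run_hierarchy(train_records, HierarchyConfig(
        hp=config.hp, seed=config.seed, canonicalize=config.canonicalize))
    stages = hier.stages

    Xtr = features_matrix(train_records)
    Xte = features_matrix(test_records)
    ytr = rf_vector(train_records)
    yte = rf_vector(test_records)

    def latent_frame(X):
        z1 = stages["stage1"].latents(X)
        z2 = stages["stage2"].latents(X)
        z3 = stages["stage3"].latents(X)
        n2 = stages["stage2"].latent_names
        n3 = stages["stage3"].latent_names
        df = pd.DataFrame({"psi": z1[:, 0], "xi": z1[:, 1],
                           "alpha": z2[:, n2.index("alpha")],
                           "beta": z2[:, n2.index("beta")]})
        for j in range(1, 6):
            df[f"gamma{j}"] = z3[:, n3.index(f"gamma{j}")]
        return df

    Ltr, Lte = latent_frame(Xtr), latent_frame(Xte)

    # The Rf target is fitted on the logit scale.  Observations saturated
    # outside (0.01, 0.99) carry no logit-scale information (their clipped
    # logits would only distort the fit with spurious curvature), so the SR
    # fit uses the unsaturated rows; held-out metrics use every sample.
    open_rows = (ytr > 0.01) & (ytr < 0.99)
    if open_rows.sum() < 10:
        open_rows = np.ones_like(open_rows, dtype=bool)

    specs = {
        "rf": dict(
            X=Ltr.loc[open_rows, ["psi", "xi"]],
            y=logit(clip_rf(ytr[open_rows])),
            X_test=Lte[["psi", "xi"]], y_test=yte, link="sigma"),
        "psi": dict(
            X=pd.DataFrame(Xtr[:, SOLVENT_SLICE], columns=list(SOLVENT_NAMES)),
            y=Ltr["psi"].to_numpy(),
            X_test=pd.DataFrame(Xte[:, SOLVENT_SLICE],
                                columns=list(SOLVENT_NAMES)),
            y_test=Lte["psi"].to_numpy(), link=None),
        "xi": dict(
            X=Ltr[["alpha", "beta"]], y=Ltr["xi"].to_numpy(),
            X_test=Lte[["alpha", "beta"]], y_test=Lte["xi"].to_numpy(),
            link=None),
        "beta": dict(
            X=Ltr[[f"gamma{j}" for j in range(1, 6)]],
            y=Ltr["beta"].to_numpy(),
            X_test=Lte[[f"gamma{j}" for j in range(1, 6)]],
            y_test=Lte["beta"].to_numpy(), link=None),
    }

    equations, fronts, pareto_json = {}, {}, {}
    for ti, target in enumerate(config.sr_targets):
        spec_ = specs[target]
        sr_cfg = replace(config.sr, seed=config.sr.seed + 31 * ti)
        front = symreg.fit(spec_["X"], spec_["y"], sr_cfg)
        sel = select(front, sr_cfg.parsimony_delta)
        pred_tr = sel.evaluate(spec_["X"])
        train_loss = float(np.mean((pred_tr - spec_["y"]) ** 2))
        pred_te = sel.evaluate(spec_["X_test"])
        if spec_["link"] == "sigma":
            pred_te = sigmoid(pred_te)
            expr_str = f"sigma({to_canonical_string(sel, precision=4)})"
        else:
            expr_str = to_canonical_string(sel, precision=4)
        m = compute_metrics(spec_["y_test"], pred_te)
        equations[target] = {
            "target": target,
            "variables": list(sel.variables()),
            "expression": expr_str,
            "complexity": sel.complexity,
            "train_loss": train_loss,
            "r2": m.r2,
            "rmse": m.rmse,
        }
        fronts[target] = front
        pareto_json[target] = _front_json(front)

    # direct network metrics of the stage-1 model, train and held-out
    net_m_tr = compute_metrics(ytr, stages["stage1"].predict(Xtr))
    net_m_te = compute_metrics(yte, stages["stage1"].predict(Xte))

    report = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_train": len(train_records),
        "n_test": len(test_records),
        "equations": equations,
        "pareto": pareto_json,
        "latent_standardization": _standardization_json(stages),
        "metrics": {"stage1_train": net_m_tr.to_dict(),
                    "stage1_test": net_m_te.to_dict()},
    }
    return RunResult(report=report, hierarchy=hier, fronts=fronts)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_reports: list          # one report dict per fold
    fold_assignments: np.ndarray  # fold index per sample
    seed: int
    config_hash: str

    @property
    def r2_per_fold(self) -> list:
        return [r["equations"]["rf"]["r2"] for r in self.fold_reports]

    @property
    def rmse_per_fold(self) -> list:
        return [r["equations"]["rf"]["rmse"] for r in self.fold_reports]


def crossvalidate(dataset, k: int = 10,
                  config: Optional[PipelineConfig] = None) -> CVResult:
    """Seeded k-fold cross-validation; each sample is tested exactly once
    and per-fold equations are reported side by side (never averaged)."""
    config = config or PipelineConfig()
    records = _records_of(dataset)
    n = len(records)
    if k > n:
        raise ConfigError(f"k={k} exceeds the {n} available samples")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    for fi, chunk in enumerate(np.array_split(perm, k)):
        assignments[chunk] = fi
    reports = []
    for fi in range(k):
        train = [records[i] for i in range(n) if assignments[i] != fi]
        test = [records[i] for i in range(n) if assignments[i] == fi]
        fold_cfg = replace(config, seed=config.seed + 1000 * (fi + 1))
        result = run_uhsr(train, fold_cfg, test_records=test)
        result.report["fold"] = fi
        reports.append(result.report)
    return CVResult(fold_reports=reports, fold_assignments=assignments,
                    seed=config.seed, config_hash=config.config_hash())


# ---------------------------------------------------------------------------
# Prediction and solvent recommendation
# ---------------------------------------------------------------------------

def predict(model: Union[TrainedStage, EquationChain],
            records: Sequence[TLCRecord]) -> np.ndarray:
    """Predicted Rf for a batch of records, order-preserving, in (0, 1)."""
    X = features_matrix(records)
    if isinstance(model, TrainedStage):
        return model.predict(X)
    if isinstance(model, EquationChain):
        return model.predict(X)
    raise SchemaError(f"cannot predict with {type(model).__name__}")


def recommend_solvent(solute: SoluteDescriptors,
                      candidates: Sequence[SolventComposition],
                      band: tuple = (0.2, 0.3),
                      model: Optional[Union[TrainedStage, EquationChain]] = None
                      ) -> list:
    """Rank candidate compositions by how close the predicted Rf falls to
    the target band (in-band distance 0); ties prefer the lower methanol
    fraction (the gentler eluent).

    Returns a sorted list of dicts with the candidate, its predicted Rf and
    its distance to the band.
    """
    if not candidates:
        raise ValidationError("empty candidate list")
    lo, hi = band
    if model is None:
        model = reference_chain(beta_mode="probe")
    records = [TLCRecord(solvent=c, solute=solute, rf=None, id=f"cand{i}")
               for i, c in enumerate(candidates)]
    rf = predict(model, records)
    ranked = []
    for c, r in zip(candidates, rf):
        dist = 0.0 if lo <= r <= hi else float(min(abs(r - lo), abs(r - hi)))
        ranked.append({"composition": c, "predicted_rf": float(r),
                       "distance": dist})
    ranked.sort(key=lambda d: (d["distance"], d["composition"].meoh))
    return ranked
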