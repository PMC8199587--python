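"""End-to-end orchestration: simulate -> bin -> normalize -> classify ->
project -> univariate screen -> risk stratification -> survival analysis.

`run_demo` regenerates the full analysis report from nothing but a seed; the
same entry point backs the command-line `demo` subcommand and the acceptance
script.  Every report is stamped with the seed and a hash of the configuration
that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _scipy_stats

from .fingerprint import (
    ClassificationResult,
    fit_fingerprint,
    loocv_evaluate,
    project,
    stratify_risk,
)
from .preprocess import pqn_normalize
from .spectra_io import BinGrid, BinnedMatrix, assemble_matrix, default_bin_grid, read_spectrum
from .synthetic_cohort import Cohort, CohortSpec, cohort_spec_from_dict, generate_cohort
from .univariate import quantify_metabolites, univariate_table
from . import survival as surv

SPECTRA_TYPES = ("NOESY", "CPMG", "Diffusion")


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run (unknown keys rejected)."""

    seed: int = 0
    outdir: str | None = None
    spectra_types: tuple[str, ...] = SPECTRA_TYPES
    k: int = 9
    var_threshold: float = 0.999
    alpha: float = 0.05
    simulate: bool = True
    spectra_dir: str | None = None
    clinical_csv: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)

    def __post_init__(self) -> None:
        for t in self.spectra_types:
            if t not in SPECTRA_TYPES:
                raise ValueError(f"unknown spectra type {t!r}")
        if not self.simulate:
            if not self.spectra_dir or not self.clinical_csv:
                raise ValueError("simulate=false requires spectra_dir and clinical_csv")
            if not Path(self.spectra_dir).is_dir():
                raise ValueError(f"spectra_dir {self.spectra_dir!r} does not exist")
            if not Path(self.clinical_csv).is_file():
                raise ValueError(f"clinical_csv {self.clinical_csv!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in raw:
            raw["cohort"] = cohort_spec_from_dict(raw["cohort"])
        if "spectra_types" in raw:
            raw["spectra_types"] = tuple(raw["spectra_types"])
        return cls(**raw)

    def hash(self) -> str:
        payload = {
            "seed": self.seed,
            "spectra_types": list(self.spectra_types),
            "k": self.k,
            "var_threshold": self.var_threshold,
            "alpha": self.alpha,
            "cohort": {
                "n": [self.cohort.n_ecrc_free, self.cohort.n_ecrc_relapsed, self.cohort.n_mcrc],
                "cv": self.cohort.concentration_cv,
                "noise_sd": self.cohort.noise_sd,
                "relapsed_metastatic_fraction": self.cohort.relapsed_metastatic_fraction,
            },
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_cohort_files(spectra_dir: str | Path, clinical_csv: str | Path):
    """Read a written cohort back: clinical table + spectra grouped by pulse sequence."""
    clinical = pd.read_csv(clinical_csv)
    spectra: dict[str, list] = {t: [] for t in SPECTRA_TYPES}
    for path in sorted(Path(spectra_dir).glob("*.tsv")):
        sp = read_spectrum(path)
        spectra.setdefault(sp.pulse_seq, []).append(sp)
    return clinical, spectra


def _subset_result(res: ClassificationResult, keep_ids: set[str]) -> ClassificationResult:
    idx = [i for i, sid in enumerate(res.sample_ids) if sid in keep_ids]
    return ClassificationResult(
        sample_ids=[res.sample_ids[i] for i in idx],
        y_true=None,
        y_pred=res.y_pred[idx],
        ca_scores=res.ca_scores[idx],
        positive_label=res.positive_label,
        negative_label=res.negative_label,
    )


def _risk_contrast_frame(clinical: pd.DataFrame, risk: pd.Series) -> pd.DataFrame:
    """eCRC covariate frame with the Table-style contrasts for Cox modelling."""
    df = clinical[clinical["group"] != "mCRC"].set_index("id").copy()
    df["risk_high"] = (risk.reindex(df.index) == "high").astype(float)
    df["stage_iii"] = df["stage"].map({"I": 0.0, "II": 0.0, "III": 1.0})
    df["grade_3"] = df["grade"].map({"1": 0.0, "2": 0.0, "3": 1.0, 1: 0.0, 2: 0.0, 3: 1.0})
    df["right_sided"] = (df["localization"] == "right").astype(float)
    df["no_adjuvant"] = (df["adjuvant_ct"] == "no").astype(float)
    return df


def run_demo(
    seed: int = 0,
    outdir: str | Path | None = None,
    spectra_types: tuple[str, ...] = SPECTRA_TYPES,
    k: int = 9,
    var_threshold: float = 0.999,
    alpha: float = 0.05,
    cohort_spec: CohortSpec | None = None,
    grid: BinGrid | None = None,
    make_figures: bool | None = None,
) -> dict:
    """Run the full analysis on a freshly simulated cohort; returns the report.

    The report carries, per spectra type, the LOOCV confusion metrics for
    relapse-free early vs metastatic discrimination; the projection summary of
    relapsed patients; the univariate metabolite screen; the metabolomic-risk
    by relapse contingency; and Kaplan-Meier / log-rank / Cox survival results
    for the early-CRC cohort split by metabolomic risk.
    """
    config = PipelineConfig(
        seed=seed, outdir=str(outdir) if outdir else None, spectra_types=tuple(spectra_types),
        k=k, var_threshold=var_threshold, alpha=alpha,
        cohort=dataclasses.replace(cohort_spec, seed=seed) if cohort_spec else CohortSpec(seed=seed),
    )
    grid = grid or default_bin_grid()
    if make_figures is None:
        make_figures = outdir is not None
    cohort = generate_cohort(config.cohort, outdir=Path(outdir) / "cohort" if outdir else None)
    clinical = cohort.clinical
    groups = clinical.set_index("id")["group"]
    free_ids = set(clinical.loc[clinical.group == "eCRC_free", "id"])
    relapsed_ids = set(clinical.loc[clinical.group == "eCRC_relapsed", "id"])

    report: dict = {"seed": seed, "config_hash": config.hash(), "loocv": {}}
    matrices: dict[str, BinnedMatrix] = {}
    loocv_results: dict[str, ClassificationResult] = {}
    for seq in config.spectra_types:
        matrix = assemble_matrix(cohort.spectra[seq], grid)
        matrices[seq] = matrix
        train_idx = [i for i, sid in enumerate(matrix.sample_ids) if sid not in relapsed_ids]
        ids = [matrix.sample_ids[i] for i in train_idx]
        y = np.array(
            ["metastatic" if groups[sid] == "mCRC" else "early" for sid in ids], dtype=object
        )
        res = loocv_evaluate(matrix.values[train_idx], y, ids, k=k, var_threshold=var_threshold)
        loocv_results[seq] = res
        report["loocv"][seq] = {
            "n": len(ids),
            "accuracy": res.accuracy,
            "sensitivity": res.sensitivity,
            "specificity": res.specificity,
            "confusion": res.confusion.tolist(),
        }

    # headline model: first spectra type (NOESY by default)
    lead = config.spectra_types[0]
    matrix = matrices[lead]
    train_idx = [i for i, sid in enumerate(matrix.sample_ids) if sid not in relapsed_ids]
    rel_idx = [i for i, sid in enumerate(matrix.sample_ids) if sid in relapsed_ids]
    train_ids = [matrix.sample_ids[i] for i in train_idx]
    y_train = np.array(
        ["metastatic" if groups[sid] == "mCRC" else "early" for sid in train_ids], dtype=object
    )
    model = fit_fingerprint(matrix.values[train_idx], y_train, k=k,
                            var_threshold=var_threshold, pulse_seq=lead)
    proj = project(model, matrix.values[rel_idx], [matrix.sample_ids[i] for i in rel_idx])
    n_pred_met = int(np.sum(proj.y_pred == "metastatic"))
    report["projection"] = {
        "spectra_type": lead,
        "n_relapsed": len(rel_idx),
        "n_predicted_metastatic": n_pred_met,
        "fraction_predicted_metastatic": n_pred_met / len(rel_idx) if rel_idx else float("nan"),
    }

    # univariate screen on the training contrast (relapse-free eCRC vs mCRC),
    # dilution-corrected with the PQN factors of the lead binned matrix
    _, pqn_report = pqn_normalize(matrix.values[train_idx])
    lead_spectra = {sp.sample_id: sp for sp in cohort.spectra[lead]}
    conc = quantify_metabolites(
        [lead_spectra[sid] for sid in train_ids],
        cohort.spec.signatures,
        dilution_factors=pqn_report.dilution_factor,
    )
    uni = univariate_table(conc, y_train, alpha=alpha)
    report["univariate"] = {
        "n_metabolites": int(len(uni)),
        "significant": uni.loc[uni.significant, "metabolite"].tolist(),
        "table": uni.to_dict(orient="records"),
    }

    # metabolomic risk for every eCRC patient: LOOCV prediction for training
    # members, projection for relapsed patients
    risk = stratify_risk(_subset_result(loocv_results[lead], free_ids), proj)
    ecrc = clinical[clinical.group != "mCRC"].copy()
    ecrc["risk"] = ecrc["id"].map(risk)
    ecrc["relapsed"] = (ecrc["group"] == "eCRC_relapsed").astype(int)
    n_hh = int(((ecrc.risk == "high") & (ecrc.relapsed == 1)).sum())
    n_hl = int(((ecrc.risk == "high") & (ecrc.relapsed == 0)).sum())
    n_lh = int(((ecrc.risk == "low") & (ecrc.relapsed == 1)).sum())
    n_ll = int(((ecrc.risk == "low") & (ecrc.relapsed == 0)).sum())
    odds, fisher_p = _scipy_stats.fisher_exact([[n_hh, n_hl], [n_lh, n_ll]])
    report["risk_stratification"] = {
        "n_high": n_hh + n_hl, "n_low": n_lh + n_ll,
        "relapse_rate_high": n_hh / (n_hh + n_hl) if n_hh + n_hl else float("nan"),
        "relapse_rate_low": n_lh / (n_lh + n_ll) if n_lh + n_ll else float("nan"),
        "fisher_odds_ratio": float(odds), "fisher_p": float(fisher_p),
    }

    # survival: RFI split by metabolomic risk
    hi = ecrc[ecrc.risk == "high"]
    lo = ecrc[ecrc.risk == "low"]
    km_high = surv.km_estimate(hi.rfi_months, hi.rfi_event)
    km_low = surv.km_estimate(lo.rfi_months, lo.rfi_event)
    chi2, logrank_p = surv.logrank_test(
        [(hi.rfi_months, hi.rfi_event), (lo.rfi_months, lo.rfi_event)]
    )
    followup = surv.reverse_km_median_followup(ecrc.os_months, ecrc.os_event)
    covs = _risk_contrast_frame(clinical, risk)
    cox_uni = surv.cox_fit(covs, "rfi_months", "rfi_event", ["risk_high"])
    step = surv.stepwise_cox(
        covs, "rfi_months", "rfi_event",
        ["risk_high", "stage_iii", "grade_3", "right_sided", "no_adjuvant"],
    )
    report["survival"] = {
        "logrank_chi2": chi2,
        "logrank_p": logrank_p,
        "median_followup_months": followup,
        "km_high_5y": km_high.survival_at(60.0),
        "km_low_5y": km_low.survival_at(60.0),
        "cox_univariate_risk": {
            "hr": float(cox_uni.table.loc["risk_high", "hr"]),
            "ci": [float(cox_uni.table.loc["risk_high", "ci_low"]),
                   float(cox_uni.table.loc["risk_high", "ci_high"])],
            "p": float(cox_uni.table.loc["risk_high", "p"]),
            "n_complete": cox_uni.n_complete,
        },
        "cox_multivariate": {
            "selected": step.selected,
            "n_complete": step.n_complete,
            "hr": {c: float(step.table.loc[c, "hr"]) for c in step.table.index},
            "p": {c: float(step.table.loc[c, "p"]) for c in step.table.index},
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for seq, m in matrices.items():
            m.to_csv(outdir / f"binned_{seq}.csv")
        uni.to_csv(outdir / "univariate.csv", index=False)
        ecrc.to_csv(outdir / "risk_stratified.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
        if make_figures:
            _write_figures(outdir, model, matrix, train_idx, rel_idx, y_train, proj, hi, lo)
    return report


def _write_figures(outdir, model, matrix, train_idx, rel_idx, y_train, proj, hi, lo) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    scores = model.clf.train_scores_
    for lbl, color in (("early", "tab:blue"), ("metastatic", "tab:red")):
        sel = y_train == lbl
        ax.scatter(scores[sel], np.random.default_rng(0).normal(0, 0.05, sel.sum()),
                   s=14, alpha=0.7, label=lbl, color=color)
    if len(proj.ca_scores):
        ax.scatter(proj.ca_scores, np.full(len(proj.ca_scores), 0.3), marker="^",
                   s=18, color="tab:green", label="relapsed (projected)")
    ax.set_xlabel("canonical score (CA1)")
    ax.set_yticks([])
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "ca_scores.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for curve, lbl, color in ((hi, "high risk", "tab:red"), (lo, "low risk", "tab:blue")):
        km = surv.km_estimate(curve.rfi_months, curve.rfi_event)
        t = np.concatenate([[0], np.repeat(km.times, 2)])
        s = np.concatenate([[1, 1], np.repeat(km.survival, 2)[:-1]])
        ax.plot(t, s, label=lbl, color=color)
    ax.set_xlabel("months")
    ax.set_ylabel("relapse-free interval probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "km_rfi_by_risk.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run from a validated config (simulation mode or files on disk)."""
    if config.simulate:
        return run_demo(
            seed=config.seed, outdir=config.outdir, spectra_types=config.spectra_types,
            k=config.k, var_threshold=config.var_threshold, alpha=config.alpha,
            cohort_spec=config.cohort,
        )
    raise NotImplementedError(
        "file-based runs are exposed through the CLI subcommands (bin/normalize/...)"
    )
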