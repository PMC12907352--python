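"""End-to-end analysis pipeline and its configuration.

Chains preprocessing, transition/sequence metrics, optional HRV coupling,
latent-class selection and the clinical-association stage, writing all
tables plus a JSON report that echoes the full configuration (every seed,
threshold and tolerance that affects results), so a report suffices to
rerun the exact analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import default_alphabet, read_event_log, segment_events
from .clinical import (
    logistic_fit,
    mediation_product,
    read_clinical,
    response_flags,
    response_rates,
)
from .errors import StageError
from .lca import assign_classes, binarize_indicators, select_classes
from .physio import PhysioSignal, behavior_indicator, cross_correlation, moving_average
from .temporal import (
    average_sequence_length,
    behavioral_entropy,
    cyclicity,
    mine_chains,
    transition_counts,
    transition_probabilities,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every knob of the pipeline in one (reportable) object."""

    events_path: str = "events.csv"
    clinical_path: str | None = None
    physio_dir: str | None = None
    output_dir: str = "playseq_out"
    alphabet_size: int = 6
    min_interval: float = 0.5  # same-category merge threshold (s)
    gap_threshold: float = 5.0  # episode delimiter for ASL (s)
    entropy_support: str = "bigram"
    chain_order: int = 2
    chain_min_support: float = 0.2
    lca_kmin: int = 2
    lca_kmax: int = 5
    lca_restarts: int = 20
    lca_tol: float = 1e-6
    lca_seed: int = 0
    binarize_rule: str = "median"
    indicator_categories: list[str] | None = None  # default: first 4 alphabet codes
    coupling_category: str = "nonverbal_initiation"
    coupling_rate: float = 10.0
    coupling_max_lag_s: float = 3.0
    coupling_window_M: int = 5
    responder_threshold: float = 0.20

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise StageError(f"config: unknown key(s) {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all stages and return (and write) the report dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    alphabet = default_alphabet(config.alphabet_size)
    report: dict[str, Any] = {
        "tool": "playseq",
        "version": __version__,
        "config": config.to_dict(),
    }

    log = _stage("load_events")(read_event_log)(config.events_path, alphabet)
    clinical = None
    if config.clinical_path is not None:
        clinical = _stage("load_clinical")(read_clinical)(config.clinical_path)

    log = _stage("preprocess")(segment_events)(log, config.min_interval)

    # --- per-child sequence metrics and group matrices
    @_stage("metrics")
    def _metrics():
        group_of = {}
        if clinical is not None:
            group_of = dict(zip(clinical["child_id"].astype(str), clinical["group"]))
        rows = []
        child_logs = {}
        for (child, _sess), events in log.sessions().items():
            child_logs.setdefault(child, []).extend(events)
        per_child = {}
        for child, events in child_logs.items():
            sub = type(log)(events=events, alphabet=alphabet)
            per_child[child] = sub
            row = {"child_id": child, "group": group_of.get(child, "NA")}
            row["n_events"] = len(sub)
            if len(sub) >= 2:
                row["entropy_bits"] = behavioral_entropy(sub, config.entropy_support).H
            else:
                row["entropy_bits"] = np.nan
            row["asl"] = average_sequence_length(sub, config.gap_threshold)
            for code in alphabet.codes:
                row[f"freq_{code}"] = sum(e.category == code for e in events)
            rows.append(row)
        metrics = pd.DataFrame(rows).sort_values("child_id", ignore_index=True)
        metrics.to_csv(out / "metrics.csv", index=False)
        # group-level transition matrices
        groups = sorted(set(metrics["group"]))
        for grp in groups:
            members = [per_child[c] for c in metrics.loc[metrics["group"] == grp, "child_id"]]
            events = [e for sub in members for e in sub.events]
            sub = type(log)(events=events, alphabet=alphabet)
            tm = transition_probabilities(transition_counts(sub))
            tm.probs_frame().to_csv(out / f"transition_{grp}.tsv", sep="\t")
        chains = mine_chains(
            list(per_child.values()), order=config.chain_order,
            min_support=config.chain_min_support,
        )
        chains.to_csv(out / "chains.csv", index=False)
        return metrics, per_child, chains

    metrics, per_child, chains = _metrics()
    report["n_children"] = int(len(metrics))
    if not chains.empty:
        report["top_chain"] = {
            "chain": chains.iloc[0]["chain"],
            "probability": float(chains.iloc[0]["probability"]),
        }

    # --- optional HRV coupling
    if config.physio_dir is not None:

        @_stage("coupling")
        def _coupling():
            rows = []
            pdir = Path(config.physio_dir)
            for child, sub in sorted(per_child.items()):
                f = pdir / f"{child}.csv"
                if not f.exists():
                    continue
                values = pd.read_csv(f)["value"].to_numpy(dtype=float)
                sig = moving_average(
                    PhysioSignal(values=values, rate=config.coupling_rate),
                    config.coupling_window_M,
                )
                sig = PhysioSignal(values=sig.values, rate=config.coupling_rate)
                b = behavior_indicator(
                    sub, config.coupling_category, config.coupling_rate, len(values)
                )
                if b.values.std() == 0 or sig.values.std() == 0:
                    continue
                max_lag = int(config.coupling_max_lag_s * config.coupling_rate)
                cc = cross_correlation(sig, b, max_lag)
                rows.append(
                    {
                        "child_id": child,
                        "peak_lag_s": cc.peak_lag / config.coupling_rate,
                        "peak_cc": cc.peak_cc,
                    }
                )
            coupling = pd.DataFrame(rows)
            coupling.to_csv(out / "coupling.csv", index=False)
            return coupling

        coupling = _coupling()
        if not coupling.empty:
            report["coupling"] = {
                "n_children": int(len(coupling)),
                "median_peak_lag_s": float(coupling["peak_lag_s"].median()),
            }

    # --- latent class analysis on binarized behavior frequencies
    @_stage("lca")
    def _lca():
        indicator_cats = config.indicator_categories or list(alphabet.codes[:4])
        freq_cols = [f"freq_{c}" for c in indicator_cats]
        freqs = metrics.set_index("child_id")[freq_cols]
        if clinical is not None:
            asd_ids = clinical.loc[clinical["group"] == "ASD", "child_id"].astype(str)
            freqs = freqs.loc[freqs.index.intersection(asd_ids)]
        X = binarize_indicators(freqs, rule=config.binarize_rule)
        sel = select_classes(
            X,
            kmin=config.lca_kmin,
            kmax=config.lca_kmax,
            restarts=config.lca_restarts,
            tol=config.lca_tol,
            seed=config.lca_seed,
        )
        sel.table.to_csv(out / "lca_selection.csv", index=False)
        labels, post = assign_classes(sel.models[sel.chosen_k], X)
        assignments = pd.DataFrame({"child_id": freqs.index, "lca_class": labels})
        assignments.to_csv(out / "lca_assignments.csv", index=False)
        return sel, assignments

    sel, assignments = _lca()
    report["lca"] = {
        "chosen_k": int(sel.chosen_k),
        "bic": {int(r.k): float(r.bic) for r in sel.table.itertuples()},
        "class_sizes": assignments["lca_class"].value_counts().sort_index().to_dict(),
    }

    # --- clinical association
    if clinical is not None:

        @_stage("clinical_association")
        def _assoc():
            asd = clinical[clinical["group"] == "ASD"].copy()
            asd["child_id"] = asd["child_id"].astype(str)
            merged = asd.merge(assignments, on="child_id", how="inner").merge(
                metrics[["child_id", "entropy_bits"]], on="child_id", how="left"
            )
            flags = response_flags(merged, config.responder_threshold)
            rates = response_rates(merged["lca_class"], flags)
            result: dict[str, Any] = {
                "response_rates_pct": {int(k): v for k, v in rates.rates.items()},
                "response_counts": {int(k): list(v) for k, v in rates.counts.items()},
            }
            if flags.nunique() > 1 and merged["lca_class"].nunique() > 1:
                try:
                    fit = logistic_fit(flags, merged["lca_class"], merged["age_months"])
                    result["odds_ratios"] = {
                        k: float(v) for k, v in fit.odds_ratios.items() if k.startswith("class")
                    }
                except Exception as exc:  # separation on small cohorts is reportable
                    result["odds_ratios_error"] = str(exc)
                med = mediation_product(
                    merged["lca_class"], merged["entropy_bits"], flags, B=200, seed=config.lca_seed
                )
                result["entropy_mediation"] = {
                    "a": med.a,
                    "b": med.b,
                    "indirect": med.indirect,
                    "ci": list(med.ci),
                }
            return result

        report["clinical"] = _assoc()

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
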