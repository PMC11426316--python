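"""End-to-end audit runs: configuration, output bundle and rate tables.

``run_audit`` chains classification, summaries and the statistical layer
into a deterministic bundle of TSV files plus a JSON run log carrying input
checksums, so a rerun with the same configuration is bit-for-bit
reproducible (timestamps live only in the log).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import classify as clf
from . import stats as st
from .authority import load_authority, load_status_registry
from .classify import SampleRecord

__all__ = ["RunConfig", "run_audit", "render_group_rates", "read_records_tsv"]

logger = logging.getLogger("seafood_audit")


@dataclass(frozen=True)
class RunConfig:
    """Inputs and toggles for one audit run."""

    records: Path
    authority: Path
    status: Path | None = None
    out_dir: Path = Path("audit_out")
    continuity_correction: bool = True
    fisher_alternative: str = "two_sided"
    seed: int = 0
    log_level: str = "INFO"
    groupings: tuple[str, ...] = ("year", "taxon_group", "cohort")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        for key in ("records", "authority", "status", "out_dir"):
            if key in raw and raw[key] is not None:
                raw[key] = Path(raw[key])
        if "groupings" in raw:
            raw["groupings"] = tuple(raw["groupings"])
        return cls(**raw)

    def validate(self) -> None:
        for label, path in (("records", self.records),
                            ("authority", self.authority)):
            if not Path(path).is_file():
                raise FileNotFoundError(f"{label} table not found: {path}")
        if self.status is not None and not Path(self.status).is_file():
            raise FileNotFoundError(f"status table not found: {self.status}")
        if self.fisher_alternative not in {"two_sided", "greater", "less"}:
            raise ValueError(
                f"unknown Fisher alternative {self.fisher_alternative!r}"
            )


def read_records_tsv(path: str | Path) -> list[SampleRecord]:
    """Read sample records from the shared TSV schema."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cohort", "year", "market_name_raw",
                "barcode_candidates"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for lineno, row in enumerate(frame.itertuples(), start=2):
        try:
            records.append(
                SampleRecord(
                    sample_id=row.sample_id,
                    year=int(row.year),
                    cohort=row.cohort,
                    market_name_raw=row.market_name_raw,
                    taxon_group=getattr(row, "taxon_group", None),
                    barcode_candidates=frozenset(
                        filter(None, row.barcode_candidates.split(";"))
                    ),
                )
            )
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"{path} line {lineno}: {exc}") from exc
    return records


def summaries_frame(summaries: list[clf.AuditSummary], by: str) -> pd.DataFrame:
    """Summaries as a frame mirroring the survey's year-table layout."""
    return pd.DataFrame(
        {
            by: s.group,
            "n": s.n,
            "semantic": s.counts["semantic"],
            "invalid_name": s.counts["invalid_name"],
            "product_substitution": s.counts["product_substitution"],
            "pct_total": round(s.pct_total_mislabeled, 1),
            "pct_conservative": round(s.pct_conservative_mislabeled, 1),
        }
        for s in summaries
    )


def render_group_rates(classified: pd.DataFrame) -> pd.DataFrame:
    """Mislabeling rates per taxon group, worst offenders first.

    One row per group with both percentages (all forms of mislabeling, and
    the conservative invalid-name/substitution estimate), sorted descending
    by the conservative rate.
    """
    if classified.empty:
        raise ValueError("no classified records")
    rows = []
    for group, sub in classified.groupby("taxon_group", dropna=True):
        n = len(sub)
        rows.append(
            {
                "taxon_group": group,
                "n": n,
                "pct_total": round(100.0 * sub["total_mislabeled"].sum() / n, 1),
                "pct_conservative": round(
                    100.0 * sub["conservative_mislabeled"].sum() / n, 1
                ),
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        ["pct_conservative", "pct_total", "taxon_group"],
        ascending=[False, False, True],
    )
    return frame.reset_index(drop=True)


def _association_tests(
    classified: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    """The audit's standard battery of 2x2 association tests."""
    pairs = [
        ("cohort", "total_mislabeled"),
        ("cohort", "conservative_mislabeled"),
        ("cohort", "precision"),
        ("precision", "conservative_mislabeled"),
    ]
    if "concern" in classified.columns:
        pairs += [
            ("concern", "conservative_mislabeled"),
            ("concern", "precision"),
        ]
    rows = []
    for row_factor, col_factor in pairs:
        try:
            table = clf.crosstab(classified, row_factor, col_factor)
        except clf.DegenerateTableError as exc:
            logger.warning("%s x %s: %s", row_factor, col_factor, exc)
            continue
        small = table.array.min() < 5
        if small:
            res = st.fisher_exact(table, alternative=config.fisher_alternative)
        else:
            res = st.chi_square_2x2(
                table, continuity_correction=config.continuity_correction
            )
        rows.append(
            {
                "row_factor": row_factor,
                "col_factor": col_factor,
                "counts": json.dumps(table.array.astype(int).tolist()),
                "n_dropped": table.n_dropped,
                "method": res.method,
                "statistic": (
                    round(res.statistic, 4) if res.statistic is not None else ""
                ),
                "df": res.df if res.df is not None else "",
                "p_value": float(f"{res.p_value:.6g}"),
                "odds_ratio": (
                    round(res.odds_ratio, 4)
                    if res.odds_ratio is not None
                    and res.odds_ratio != float("inf")
                    else res.odds_ratio
                ),
                "ci": "" if res.ci is None else f"{res.ci[0]:.3g}-{res.ci[1]:.3g}",
            }
        )
    return pd.DataFrame(rows)


def _glm_report(classified: pd.DataFrame) -> pd.DataFrame:
    """Precision x accuracy logistic regression on conservation concern."""
    usable = classified[
        (classified["precision"] != "excluded")
        & (classified["concern"] != "excluded")
    ]
    if usable.empty or usable["concern"].nunique() < 2:
        raise ValueError(
            "no usable records for the conservation model (need both "
            "concern classes after exclusions)"
        )
    precision = (usable["precision"] == "ambiguous").to_numpy(float)
    accuracy = usable["conservative_mislabeled"].to_numpy(float)
    y = (usable["concern"] == "concern").to_numpy(float)
    fits = []
    for interaction in (True, False):
        X, names = st.logistic_design(precision, accuracy, interaction)
        fits.append(st.fit_logistic(X, y, names))
    ranked = st.compare_models(fits)
    rows = []
    for fit, delta in ranked:
        model = "+".join(fit.term_names[1:])
        for i, name in enumerate(fit.term_names):
            rows.append(
                {
                    "model": model,
                    "n": fit.n_obs,
                    "term": name,
                    "beta": round(float(fit.coefficients[i]), 4),
                    "se": round(float(fit.standard_errors[i]), 4),
                    "z": round(float(fit.z_values[i]), 4),
                    "p": float(f"{fit.p_values[i]:.4g}"),
                    "odds_ratio": round(float(fit.odds_ratios[i]), 4),
                    "or_ci_low": round(float(fit.odds_ratio_ci[i, 0]), 4),
                    "or_ci_high": round(float(fit.odds_ratio_ci[i, 1]), 4),
                    "importance": round(abs(float(fit.z_values[i])), 4),
                    "vif": round(fit.vif.get(name, float("nan")), 4),
                    "aic": round(fit.aic, 2),
                    "aicc": round(fit.aicc, 2),
                    "delta_aicc": round(delta, 2),
                    "mcfadden_r2": round(fit.mcfadden_r2, 4),
                }
            )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_audit(config: RunConfig) -> dict[str, Path]:
    """Run the full audit and write the report bundle.

    Outputs: ``classified.tsv`` (per-record categories and rationales),
    ``summary.tsv`` plus one summary per requested grouping,
    ``group_rates.tsv``, ``stats.tsv``, ``glm_report.tsv`` (when a status
    table is supplied) and ``run_log.json``.  A failure removes nothing but
    leaves a ``FAILED`` marker so partial bundles are recognizable.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "FAILED"
    marker.write_text("run in progress\n", encoding="utf-8")
    try:
        records = read_records_tsv(config.records)
        authority = load_authority(str(config.authority))
        registry = (
            load_status_registry(str(config.status))
            if config.status is not None
            else None
        )
        classified = clf.classify_all(records, authority, registry)
        outputs: dict[str, Path] = {}

        def write(name: str, frame: pd.DataFrame) -> None:
            path = out / name
            frame.to_csv(path, sep="\t", index=False)
            outputs[name] = path

        write("classified.tsv", classified)
        write("summary.tsv", summaries_frame(clf.summarize(classified), "all"))
        for by in config.groupings:
            write(
                f"summary_by_{by}.tsv",
                summaries_frame(clf.summarize(classified, by=by), by),
            )
        write("group_rates.tsv", render_group_rates(classified))
        write("stats.tsv", _association_tests(classified, config))
        if registry is not None:
            write("glm_report.tsv", _glm_report(classified))
        log = {
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "inputs": {
                "records": {"path": str(config.records),
                            "sha256": _sha256(config.records)},
                "authority": {"path": str(config.authority),
                              "sha256": _sha256(config.authority)},
                "status": (
                    {"path": str(config.status), "sha256": _sha256(config.status)}
                    if config.status is not None
                    else None
                ),
            },
            "n_records": len(records),
            "seed": config.seed,
            "outputs": sorted(outputs),
        }
        (out / "run_log.json").write_text(
            json.dumps(log, indent=2) + "\n", encoding="utf-8"
        )
        marker.unlink()
        return outputs
    except Exception:
        marker.write_text("run failed; bundle is incomplete\n", encoding="utf-8")
        raise
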