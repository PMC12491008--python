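"""End-to-end assessment runs and report writing.

``run_assessment`` chains the stages — load/QC composition, score and rank,
band distributions, minimal daily portions at every target tier, stratified
intake with adequacy flags — and collects everything into tidy DataFrames.
The report layer only formats; every number it emits is produced by an
operation in the other modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import composition, intake, requirements, synthetic
from .content import (
    Band,
    Omega3Basis,
    band_distribution,
    rank_by_content,
    score_table,
)
from .records import Category, ConfigError, ContractError, DataError
from .requirements import (
    Authority,
    EPA_DHA_TIERS,
    LifeStage,
    Nutrient,
    Sex,
    lookup_reference,
    minimal_required_consumption,
)

__all__ = ["RunConfig", "ReportBundle", "run_assessment"]


class RunConfig(BaseModel):
    """Configuration of one assessment run.

    ``composition`` and ``consumption`` are either the selectors
    ``"bundled"`` / ``"synthetic"`` or paths to delimited-text inputs.
    """

    model_config = ConfigDict(extra="forbid")

    composition: str = "bundled"
    consumption: str = "synthetic"
    authority_ala: Authority = Authority.NIH
    authority_epa_dha: Authority = Authority.WHO
    tiers: tuple[float, ...] = EPA_DHA_TIERS
    conversion_rate: float = Field(default=requirements.DEFAULT_CONVERSION_RATE, ge=0.0, le=1.0)
    oz_grams: float = Field(default=requirements.OZ_AVOIRDUPOIS_G, gt=0.0)
    basis: Omega3Basis = Omega3Basis.TOTAL
    top_n: int = Field(default=10, ge=1)
    seed: int = 0
    n_synthetic: int = Field(default=500, ge=1)
    out_dir: Path | None = None

    @field_validator("tiers")
    @classmethod
    def _positive_tiers(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if not v or any(t <= 0 for t in v):
            raise ValueError("tiers must be positive g/day values")
        return v

    @field_validator("composition", "consumption")
    @classmethod
    def _path_exists(cls, v: str) -> str:
        if v not in ("bundled", "synthetic") and not Path(v).exists():
            raise ValueError(f"input path does not exist: {v}")
        return v


@dataclass
class ReportBundle:
    """All tables of one run, machine-readable, plus the run log."""

    scored: pd.DataFrame
    rankings: pd.DataFrame
    dmrc: pd.DataFrame
    band_distributions: pd.DataFrame
    intake_ala: pd.DataFrame
    intake_epa_dha: pd.DataFrame
    qc_findings: pd.DataFrame
    run_log: dict = field(default_factory=dict)

    def frames(self) -> Mapping[str, pd.DataFrame]:
        return {
            "scored": self.scored,
            "rankings": self.rankings,
            "dmrc": self.dmrc,
            "band_distributions": self.band_distributions,
            "intake_ala": self.intake_ala,
            "intake_epa_dha": self.intake_epa_dha,
            "qc_findings": self.qc_findings,
        }

    def write(self, out_dir: str | Path) -> None:
        """Emit every table as TSV (full precision) and aligned text."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.frames().items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
            pretty = df.copy()
            for col in pretty.columns:
                if pd.api.types.is_float_dtype(pretty[col]):
                    decimals = 2 if col.endswith("_g_per_g") or col == "content_display" else 3
                    pretty[col] = pretty[col].map(lambda x: f"{x:.{decimals}f}")
            (out / f"{name}.txt").write_text(pretty.to_string(index=False) + "\n", encoding="utf-8")
        (out / "run_log.json").write_text(
            json.dumps(self.run_log, indent=2, default=str) + "\n", encoding="utf-8"
        )


def _load_composition(config: RunConfig) -> dict[str, composition.CompositionTable]:
    if config.composition == "bundled":
        return composition.load_all_bundled()
    table = composition.load_composition_table(config.composition)
    return {"user": table}


def _load_strata(config: RunConfig) -> list[intake.ConsumptionStratum]:
    if config.consumption == "synthetic":
        spec = synthetic.taiwan_like_spec(n_per_cell=config.n_synthetic, seed=config.seed)
        _, strata = synthetic.generate_consumption(spec)
        return strata
    return intake.load_consumption_table(config.consumption)


def _stage(name: str):
    """Tag stage errors with the stage name for actionable diagnostics."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, (ConfigError, DataError, ContractError)):
                exc.args = (f"[stage: {name}] {exc}",)
            return False

    return _Ctx()


def run_assessment(config: RunConfig) -> ReportBundle:
    """Run the full pipeline under one configuration."""
    with _stage("composition"):
        tables = _load_composition(config)
        records = [r for t in tables.values() for r in t]

    with _stage("qc"):
        findings = []
        for t in tables.values():
            findings.extend(composition.validate_and_qc(t))
        qc_df = pd.DataFrame(
            [
                {
                    "food_id": f.food_id,
                    "field": f.field_name,
                    "listed": f.listed_value,
                    "recomputed": f.recomputed_value,
                    "severity": f.severity.value,
                    "message": f.message,
                }
                for f in findings
            ],
            columns=["food_id", "field", "listed", "recomputed", "severity", "message"],
        )

    with _stage("scoring"):
        scored = score_table(records, config.basis)
        scored_df = pd.DataFrame(
            {
                "food_id": [c.food_id for c in scored],
                "name": [c.name for c in scored],
                "category": [c.category.value for c in scored],
                "content_exact": [c.content_exact for c in scored],
                "content_display": [c.content_display for c in scored],
                "band": [c.band.value for c in scored],
            }
        )

    with _stage("ranking"):
        rank_rows = []
        for cat in Category:
            members = [c for c in scored if c.category == cat]
            if not members:
                continue
            for pos, c in enumerate(rank_by_content(members, config.top_n), start=1):
                rank_rows.append(
                    {
                        "category": cat.value,
                        "rank": pos,
                        "food_id": c.food_id,
                        "name": c.name,
                        "content_exact": c.content_exact,
                        "content_display": c.content_display,
                    }
                )
        rankings_df = pd.DataFrame(rank_rows)

    with _stage("bands"):
        band_rows = []
        for cat in Category:
            if not any(c.category == cat for c in scored):
                continue
            dist = band_distribution(scored, cat)
            for band in Band:
                band_rows.append(
                    {
                        "category": cat.value,
                        "band": band.value,
                        "count": dist.counts[band],
                        "fraction": dist.fractions[band],
                    }
                )
        bands_df = pd.DataFrame(band_rows)

    with _stage("dmrc"):
        targets: list[tuple[Nutrient, str, float, tuple[Category, ...]]] = [
            (
                Nutrient.ALA,
                "ALA male adult",
                lookup_reference(
                    Nutrient.ALA, config.authority_ala, Sex.MALE, 30.0
                ).amount_low,
                intake.NUTRIENT_CATEGORIES[Nutrient.ALA],
            ),
            (
                Nutrient.ALA,
                "ALA female adult",
                lookup_reference(
                    Nutrient.ALA, config.authority_ala, Sex.FEMALE, 30.0
                ).amount_low,
                intake.NUTRIENT_CATEGORIES[Nutrient.ALA],
            ),
        ]
        for tier in config.tiers:
            targets.append(
                (
                    Nutrient.EPA_DHA,
                    f"EPA+DHA {tier:g} g",
                    tier,
                    intake.NUTRIENT_CATEGORIES[Nutrient.EPA_DHA],
                )
            )
        dmrc_rows = []
        for nutrient, label, amount, cats in targets:
            for c in scored:
                if c.category not in cats or c.content_exact <= 0:
                    continue
                req = minimal_required_consumption(c, amount, nutrient)
                dmrc_rows.append(
                    {
                        "target": label,
                        "target_g_day": amount,
                        "food_id": c.food_id,
                        "name": c.name,
                        "category": c.category.value,
                        "grams_exact": req.grams_exact,
                        "grams_rounded": req.grams_rounded,
                    }
                )
        dmrc_df = pd.DataFrame(dmrc_rows).sort_values(
            ["target", "grams_exact"], kind="stable"
        ).reset_index(drop=True)

    with _stage("intake"):
        strata = _load_strata(config)
        contents = {
            cat: intake.category_mean_content(scored, cat)
            for cats in intake.NUTRIENT_CATEGORIES.values()
            for cat in cats
            if any(c.category == cat for c in scored)
        }
        intake_frames: dict[Nutrient, pd.DataFrame] = {}
        for nutrient, authority in (
            (Nutrient.ALA, config.authority_ala),
            (Nutrient.EPA_DHA, config.authority_epa_dha),
        ):
            rows = []
            for stratum in strata:
                est = intake.estimate_intake(stratum, contents, nutrient)
                ref = intake.reference_for_stratum(stratum, nutrient, authority)
                flags = intake.assess_adequacy(est, ref)
                for cat, contrib in est.contributions.items():
                    rows.append(
                        {
                            "sex": stratum.sex.value,
                            "age_low": stratum.age_low,
                            "age_high": stratum.age_high,
                            "category": cat.value,
                            **contrib,
                        }
                    )
                rows.append(
                    {
                        "sex": stratum.sex.value,
                        "age_low": stratum.age_low,
                        "age_high": stratum.age_high,
                        "category": "all",
                        **est.totals,
                        "reference_g_day": ref.amount_low,
                        **{f"{s}_adequate": flags[s] for s in intake.STATISTICS},
                    }
                )
            intake_frames[nutrient] = pd.DataFrame(rows)

    run_log = {
        "config": config.model_dump(mode="json"),
        "seed": config.seed,
        "n_records": len(records),
        "n_strata": len(strata),
        "n_qc_findings": len(findings),
    }
    bundle = ReportBundle(
        scored=scored_df,
        rankings=rankings_df,
        dmrc=dmrc_df,
        band_distributions=bands_df,
        intake_ala=intake_frames[Nutrient.ALA],
        intake_epa_dha=intake_frames[Nutrient.EPA_DHA],
        qc_findings=qc_df,
        run_log=run_log,
    )
    if config.out_dir is not None:
        bundle.write(config.out_dir)
    return bundle
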