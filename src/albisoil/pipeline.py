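"""End-to-end run: simulate -> SQI -> treatment stats -> community ecology.

A :class:`RunConfig` fully determines a run; the JSON report embeds the
resolved config and a single top-level seed fans out to fixed per-stage
offsets (soil +0, community +1, PERMANOVA +2, Mantel +3, envfit +4) so each
stage is reproducible standalone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import ecology, sqi, stats
from .errors import ParameterError
from .soil_tables import TreatmentDesign, zscore
from .synthetic_data import (
    EffectProfile,
    generate_community_table,
    generate_soil_table,
    paper_profile,
)

__all__ = ["RunConfig", "run_pipeline", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1

# per-sequencing-sample read depth used to turn relative abundances into
# pseudo-counts for Chao1 (richness needs counts, not proportions)
CHAO1_DEPTH = 20_000

# the Total Data Set designated for soil quality assessment
SQI_TDS = ("pH", "TP", "TN", "TK", "AP", "AK", "S-β-GC", "S-UE", "S-CL", "S-Lip")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    profile: str = "paper"  # "paper" or a path to a YAML profile
    seed: int = 42
    noise_cv: float = 0.08
    n_replicates: int | None = None
    n_taxa: int = 40
    alpha_mds: float = 0.01
    alpha_letters: float = 0.05
    n_perm: int = 999
    out_dir: str | None = None

    def validate(self) -> None:
        if self.noise_cv < 0:
            raise ParameterError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.n_perm < 99:
            raise ParameterError(f"n_perm must be >= 99, got {self.n_perm}")
        if not (0 < self.alpha_mds < 1 and 0 < self.alpha_letters < 1):
            raise ParameterError("alpha levels must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def resolve_profile(self, noise_cv: float, seed: int) -> EffectProfile:
        if self.profile == "paper":
            return paper_profile(noise_cv=noise_cv, seed=seed)
        with open(self.profile, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return EffectProfile(
            baseline_means=raw["baseline_means"],
            effect_multipliers=raw.get("effect_multipliers", {}),
            taxa_targets=raw.get("taxa_targets", {}),
            noise_cv=noise_cv,
            seed=seed,
        )


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the machine-readable report.

    Identical config (including seed) gives a byte-identical report; when
    ``config.out_dir`` is set, the soil/community tables, the SQI scores
    and the report JSON are written there and their checksums recorded.
    """
    config.validate()
    design = TreatmentDesign()
    profile = config.resolve_profile(config.noise_cv, config.seed)

    soil = generate_soil_table(
        profile, design, n_replicates=config.n_replicates, seed=config.seed
    )
    community = generate_community_table(
        profile,
        design,
        n_taxa=config.n_taxa,
        n_replicates=config.n_replicates,
        seed=config.seed + 1,
    )

    # --- treatment contrasts and ANOVA per indicator -----------------------
    control = design.control
    means = soil.treatment_means()
    pct = {
        ind: {
            t: stats.percent_change(means.loc[t, ind], means.loc[control, ind])
            for t in design.treatments
            if t != control
        }
        for ind in soil.indicator_names
    }

    amf, tricho = design.factor_levels(soil.treatments)
    anova_report = {}
    for ind in soil.indicator_names:
        vals = soil.data[ind].to_numpy()
        one = stats.one_way_anova(vals, soil.treatments.to_numpy())
        letters = None
        if one.status == "ok" and np.isfinite(one.table.loc["between", "F"]):
            letters = stats.duncan_letters(
                one.group_means.to_dict(),
                mse=float(one.table.loc["within", "MS"]),
                df=int(one.table.loc["within", "df"]),
                n_per_group=int(soil.n_samples / len(design.treatments)),
                alpha=config.alpha_letters,
            )
        two = stats.two_way_anova(vals, amf, tricho)
        anova_report[ind] = {
            "one_way": {
                "F": float(one.table.loc["between", "F"]),
                "p": float(one.table.loc["between", "p"]),
            },
            "letters": letters,
            "two_way_p": {
                "amf": float(two.table.loc["A", "p"]),
                "trichoderma": float(two.table.loc["B", "p"]),
                "interaction": float(two.table.loc["A:B", "p"]),
            },
        }

    # --- soil quality index -------------------------------------------------
    # score on the designated assessment indicators; constant (zero-variance)
    # columns cannot enter a correlation PCA and are excluded with a note
    tds = [c for c in SQI_TDS if c in soil.indicator_names] or soil.indicator_names
    sds = soil.data[tds].std(ddof=1)
    excluded_constant = [c for c in tds if sds[c] == 0]
    sqi_table = soil.subset([c for c in tds if sds[c] > 0])
    selection = sqi.select_mds(sqi_table, alpha=config.alpha_mds)
    sqi_res = sqi.compute_sqi(sqi_table, selection)

    # --- community ecology ----------------------------------------------------
    shannon_by_sample = {
        sid: ecology.shannon(row)
        for sid, row in zip(community.sample_ids, community.values)
    }
    chao1_by_sample = {
        sid: ecology.chao1(np.round(row * CHAO1_DEPTH), rounding=True)
        for sid, row in zip(community.sample_ids, community.values)
    }
    dist = ecology.bray_curtis(community)
    ordination = ecology.pcoa(dist)
    perma = ecology.permanova(
        dist, community.treatments.to_numpy(), n_perm=config.n_perm, seed=config.seed + 2
    )
    all_sds = soil.data.std(ddof=1)
    varying = [c for c in soil.indicator_names if all_sds[c] > 0]
    env_dist = ecology.euclidean_distance(zscore(soil.subset(varying)).data)
    man = ecology.mantel(dist, env_dist, n_perm=config.n_perm, seed=config.seed + 3)
    rda_vars = [c for c in ("pH", "SOM", "TN", "TP") if c in varying]
    rda_res = ecology.rda(community, soil.subset(rda_vars))
    env_fits = {}
    for k, ind in enumerate(rda_vars):
        fit = ecology.envfit(
            ordination,
            soil.data[ind].to_numpy(),
            n_perm=config.n_perm,
            seed=config.seed + 4 + k,
        )
        env_fits[ind] = {"R2": fit.r2, "p": fit.p}

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": asdict(config),
        "percent_change": pct,
        "anova": anova_report,
        "sqi": {
            "tds": list(sqi_table.indicator_names),
            "excluded_constant": excluded_constant,
            "final_set": selection.final_set,
            "norms": {k: float(v) for k, v in selection.norms.items()},
            "weights": {k: float(v) for k, v in sqi_res.weights.items()},
            "treatment_means": {k: float(v) for k, v in sqi_res.treatment_means.items()},
            "percent_change_vs_control": {
                k: float(v) for k, v in sqi_res.percent_change_vs_control.items()
            },
            "audit_log": selection.audit_log,
        },
        "diversity": {
            "shannon": shannon_by_sample,
            "chao1": chao1_by_sample,
            "chao1_depth": CHAO1_DEPTH,
        },
        "pcoa": {
            "percent_explained": [float(v) for v in ordination.percent_explained[:4]],
            "negative_eigenvalue_mass": ordination.negative_eigenvalue_mass,
        },
        "permanova": {"pseudo_F": perma.pseudo_f, "p": perma.p, "status": perma.status},
        "mantel": {"r": man.r, "p": man.p},
        "rda": {
            "percent_explained": [float(v) for v in rda_res.percent_explained[:4]],
            "envfit": env_fits,
        },
    }
    report = _round_floats(report)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        soil.to_csv(out / "soil.csv")
        community.to_csv(out / "community.csv")
        sqi_res.sqi.rename("sqi").to_csv(out / "sqi.csv", encoding="utf-8")
        ordination.scores.to_csv(out / "pcoa_scores.csv", encoding="utf-8")
        checksums = {
            name: _sha256(out / name)
            for name in ("soil.csv", "community.csv", "sqi.csv", "pcoa_scores.csv")
        }
        report["output_checksums"] = checksums
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return report
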