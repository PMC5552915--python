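"""Run configuration.

A :class:`RunConfig` holds everything one screening run needs: the gene
families (reference FASTA per family, target vs housekeeping role), the
site manifest (CDS FASTA paths and low/high pH group label per site),
and the numeric knobs — acceptance threshold in bits, the reference
length statistic, the t-test variant, alpha, per-family copy numbers and
the random seed.  Configs load from and save to YAML.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io import PhoscanError

#: the five single-copy housekeeping families used for genome equivalents
HOUSEKEEPING_FAMILIES = ("RecA", "RpoB", "AtpB", "GyrB", "SucD")
#: the normalization anchor
ANCHOR_FAMILY = "RecA"
#: the three alkaline phosphatase families
APASE_FAMILIES = ("PhoX", "PhoD", "PhoA")

LOW_PH = "low_pH"
HIGH_PH = "high_pH"


class ConfigError(PhoscanError):
    """Invalid run configuration."""


@dataclass
class FamilyConfig:
    name: str
    reference_path: str
    role: str  # "target" | "housekeeping"
    copy_number: float = 1.0


@dataclass
class SiteConfig:
    site_id: str
    cds_paths: list[str]
    group: str  # LOW_PH | HIGH_PH


@dataclass
class RunConfig:
    families: dict[str, FamilyConfig] = field(default_factory=dict)
    sites: dict[str, SiteConfig] = field(default_factory=dict)
    threshold_bits: float = 25.0
    reference_statistic: str = "median"  # "median" | "mean"
    ttest_variant: str = "pooled"  # "pooled" | "welch"
    alpha: float = 0.05
    seed: int = 0
    occupancy_threshold: float = 0.5
    pseudocount: float = 1.0
    alignment_mode: str = "local"  # "local" | "global"
    normalization_direction: str = "divide_by_ratio"  # or "multiply_by_ratio"
    housekeeping: tuple[str, ...] = HOUSEKEEPING_FAMILIES
    multiple_testing: str = "none"  # "none" | "bh"
    refdb_path: str | None = None
    min_align_score: float = 50.0
    max_taxonomy_hits_per_site: int = 100
    output_dir: str = "phoscan_out"

    # ----- validation -------------------------------------------------
    def validate(self) -> None:
        hk = [f for f in self.families.values() if f.role == "housekeeping"]
        targets = [f for f in self.families.values() if f.role == "target"]
        if not any(f.name == ANCHOR_FAMILY for f in hk):
            raise ConfigError(
                f"housekeeping families must include the normalization anchor "
                f"{ANCHOR_FAMILY!r}"
            )
        if sum(f.name == ANCHOR_FAMILY for f in self.families.values()) != 1:
            raise ConfigError(f"exactly one family may be named {ANCHOR_FAMILY!r}")
        if not targets:
            raise ConfigError("at least one target family is required")
        for site in self.sites.values():
            if site.group not in (LOW_PH, HIGH_PH):
                raise ConfigError(
                    f"site {site.site_id!r}: group must be {LOW_PH!r} or "
                    f"{HIGH_PH!r}, got {site.group!r}"
                )
            if not site.cds_paths:
                raise ConfigError(f"site {site.site_id!r}: no CDS files listed")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.reference_statistic not in ("median", "mean"):
            raise ConfigError(f"bad reference_statistic {self.reference_statistic!r}")
        if self.ttest_variant not in ("pooled", "welch"):
            raise ConfigError(f"bad ttest_variant {self.ttest_variant!r}")
        if self.alignment_mode not in ("local", "global"):
            raise ConfigError(f"bad alignment_mode {self.alignment_mode!r}")
        if self.normalization_direction not in ("divide_by_ratio", "multiply_by_ratio"):
            raise ConfigError(
                f"bad normalization_direction {self.normalization_direction!r}"
            )
        for fam in self.housekeeping:
            if fam not in self.families:
                raise ConfigError(f"housekeeping family missing from manifest: {fam}")
        for fam in self.families.values():
            if fam.copy_number < 1:
                raise ConfigError(f"family {fam.name}: copy_number must be >= 1")

    # ----- helpers ----------------------------------------------------
    @property
    def target_families(self) -> list[str]:
        return [f.name for f in self.families.values() if f.role == "target"]

    def sites_in_group(self, group: str) -> list[str]:
        return [s.site_id for s in self.sites.values() if s.group == group]

    # ----- serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "families": {
                name: {
                    "reference": f.reference_path,
                    "role": f.role,
                    "copy_number": f.copy_number,
                }
                for name, f in self.families.items()
            },
            "sites": {
                sid: {"cds": list(s.cds_paths), "group": s.group}
                for sid, s in self.sites.items()
            },
            "parameters": {
                "threshold_bits": self.threshold_bits,
                "reference_statistic": self.reference_statistic,
                "ttest_variant": self.ttest_variant,
                "alpha": self.alpha,
                "seed": self.seed,
                "occupancy_threshold": self.occupancy_threshold,
                "pseudocount": self.pseudocount,
                "alignment_mode": self.alignment_mode,
                "normalization_direction": self.normalization_direction,
                "housekeeping": list(self.housekeeping),
                "multiple_testing": self.multiple_testing,
                "refdb": self.refdb_path,
                "min_align_score": self.min_align_score,
                "max_taxonomy_hits_per_site": self.max_taxonomy_hits_per_site,
                "output_dir": self.output_dir,
            },
        }

    @classmethod
    def from_dict(cls, data: dict, base_dir: str | Path | None = None) -> "RunConfig":
        base = Path(base_dir) if base_dir is not None else None

        def _resolve(p):
            if p is None:
                return None
            p = Path(p)
            if base is not None and not p.is_absolute():
                p = base / p
            return str(p)

        families = {}
        for name, f in data.get("families", {}).items():
            families[name] = FamilyConfig(
                name=name,
                reference_path=_resolve(f["reference"]),
                role=f.get("role", "target"),
                copy_number=float(f.get("copy_number", 1.0)),
            )
        sites = {}
        for sid, s in data.get("sites", {}).items():
            sites[sid] = SiteConfig(
                site_id=sid,
                cds_paths=[_resolve(p) for p in s.get("cds", [])],
                group=s.get("group", ""),
            )
        params = data.get("parameters", {})
        cfg = cls(families=families, sites=sites)
        simple = {
            "threshold_bits": float,
            "reference_statistic": str,
            "ttest_variant": str,
            "alpha": float,
            "seed": int,
            "occupancy_threshold": float,
            "pseudocount": float,
            "alignment_mode": str,
            "normalization_direction": str,
            "multiple_testing": str,
            "min_align_score": float,
            "max_taxonomy_hits_per_site": int,
            "output_dir": str,
        }
        for key, cast in simple.items():
            if key in params and params[key] is not None:
                setattr(cfg, key, cast(params[key]))
        if params.get("output_dir"):
            cfg.output_dir = _resolve(params["output_dir"])
        if "housekeeping" in params:
            cfg.housekeeping = tuple(params["housekeeping"])
        if params.get("refdb"):
            cfg.refdb_path = _resolve(params["refdb"])
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wt") as out:
            yaml.safe_dump(self.to_dict(), out, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as handle:
            data = yaml.safe_load(handle)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a YAML mapping")
        return cls.from_dict(data, base_dir=path.parent)

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
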