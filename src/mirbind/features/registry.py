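"""Config-driven feature registry and the featurize entry point."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from mirbind.features import families
from mirbind.features.fold import NussinovFoldBackend
from mirbind.sequence_io import ResourceBundle
from mirbind.types import CandidateSite, MiRNA, TranscriptUTR

FAMILY_NAMES = (
    "site_type",
    "stability",
    "accessibility",
    "supplementary",
    "conservation",
    "snp",
    "descriptor",
)

_FAMILY_MEMBERS: Dict[str, List[str]] = {
    "site_type": families.SITE_TYPE_NAMES,
    "stability": families.STABILITY_NAMES,
    "accessibility": families.ACCESSIBILITY_NAMES,
    "supplementary": families.SUPPLEMENTARY_NAMES,
    "conservation": families.CONSERVATION_NAMES,
    "snp": families.SNP_NAMES,
    "descriptor": families.DESCRIPTOR_NAMES,
}


@dataclass
class RegistryConfig:
    """Tunable parameters of the feature computations."""

    flank: int = 20                 # target_region flank around the site
    acc_flank: int = 30             # AU-fraction flank width
    acc_window: int = 10            # +/- window for unpaired propensity
    cons_flank: int = 30
    cons_threshold: float = 0.5
    fold_window: int = 25
    use_fold_backend: bool = True
    families: Tuple[str, ...] = FAMILY_NAMES

    def to_dict(self) -> dict:
        d = asdict(self)
        d["families"] = list(self.families)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RegistryConfig":
        d = dict(d)
        if "families" in d:
            d["families"] = tuple(d["families"])
        return cls(**d)


class FeatureRegistry:
    """Ordered, named feature set with per-family computation handles."""

    def __init__(
        self,
        config: Optional[RegistryConfig] = None,
        feature_names: Optional[Sequence[str]] = None,
    ):
        self.config = config or RegistryConfig()
        for fam in self.config.families:
            if fam not in FAMILY_NAMES:
                raise ValueError(f"unknown feature family {fam!r}")
        full = [
            name
            for fam in FAMILY_NAMES
            if fam in self.config.families
            for name in _FAMILY_MEMBERS[fam]
        ]
        if feature_names is None:
            self.feature_names = list(full)
        else:
            unknown = set(feature_names) - set(full)
            if unknown:
                raise ValueError(f"unknown feature names: {sorted(unknown)}")
            self.feature_names = list(feature_names)
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        self._fold = (
            NussinovFoldBackend(window=self.config.fold_window)
            if self.config.use_fold_backend
            else None
        )

    def __len__(self) -> int:
        return len(self.feature_names)

    def family_of(self, name: str) -> str:
        for fam, members in _FAMILY_MEMBERS.items():
            if name in members:
                return fam
        raise KeyError(name)

    def subset(self, feature_names: Sequence[str]) -> "FeatureRegistry":
        return FeatureRegistry(self.config, feature_names)

    def fingerprint(self) -> str:
        return json.dumps(
            {"config": self.config.to_dict(), "features": self.feature_names},
            sort_keys=True,
        )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {"config": self.config.to_dict(), "features": self.feature_names}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureRegistry":
        return cls(RegistryConfig.from_dict(d["config"]), d.get("features"))

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "FeatureRegistry":
        return cls.from_dict(json.loads(Path(path).read_text()))


def featurize(
    site: CandidateSite,
    mirna: MiRNA,
    utr: TranscriptUTR,
    registry: FeatureRegistry,
    resources: Optional[ResourceBundle] = None,
) -> Dict[str, float]:
    """Full named feature vector for one site; absent resources give NaN."""
    cfg = registry.config
    needed = {registry.family_of(n) for n in registry.feature_names}
    values: Dict[str, float] = {}
    if "site_type" in needed:
        values.update(families.site_type_features(site))
    if "stability" in needed:
        values.update(families.stability_features(mirna, site))
    if "accessibility" in needed:
        values.update(
            families.accessibility_features(
                utr.sequence, site, registry._fold,
                flank=cfg.acc_flank, window=cfg.acc_window,
            )
        )
    if "supplementary" in needed:
        values.update(
            families.supplementary_pairing_features(mirna, utr.sequence, site)
        )
    if "conservation" in needed:
        track = None
        if resources is not None:
            track = resources.conservation.get(site.transcript_id)
        values.update(
            families.conservation_features(
                track, site, flank=cfg.cons_flank, threshold=cfg.cons_threshold
            )
        )
    if "snp" in needed:
        snps = resources.snps if resources is not None else None
        values.update(families.snp_features(snps, site))
    if "descriptor" in needed:
        values.update(families.descriptor_features(site.target_region))
    return {name: values[name] for name in registry.feature_names}


META_COLUMNS = ["mirna_id", "transcript_id", "gene_id", "start", "end", "site_type"]


def featurize_many(
    sites: Sequence[CandidateSite],
    resources: ResourceBundle,
    registry: FeatureRegistry,
) -> pd.DataFrame:
    """Feature matrix with site metadata columns, one row per site."""
    rows = []
    for site in sites:
        mirna = resources.mirna_by_id(site.mirna_id)
        utr = resources.utr_by_transcript(site.transcript_id)
        row = {
            "mirna_id": site.mirna_id,
            "transcript_id": site.transcript_id,
            "gene_id": utr.gene_id,
            "start": site.start,
            "end": site.end,
            "site_type": site.site_type,
        }
        row.update(featurize(site, mirna, utr, registry, resources))
        rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + registry.feature_names)
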