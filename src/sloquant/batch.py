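"""Batch orchestration: run the protocol over a cohort manifest.

A run is fully determined by (manifest, image files, RunConfig): every
output row carries a hash of the configuration and of the input image
bytes, so any number in the cohort table can be traced back to exactly
what produced it. Per-image manual threshold overrides are supplied as a
CSV keyed by (animal_id, eye, week) — the scripted, auditable equivalent
of the blinded evaluator's manual adjustment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import measure, score
from .imgio import ImageMeta, read_image, read_manifest
from .measure import ProtocolConfig
from .preprocess import PreprocessConfig

log = logging.getLogger("sloquant")

COHORT_COLUMNS = ("animal_id", "eye", "week", "group",
                  "cc", "sua", "mvi", "mcb", "ava",
                  "config_hash", "image_sha256")


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of a full batch run."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    manual_thresholds: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["manual_thresholds"] = {k: list(v) for k, v in
                                  self.manual_thresholds.items()}
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        proto = d.get("protocol", {})
        pre = PreprocessConfig(**proto.pop("preprocess", {}))
        manual = proto.pop("manual_threshold", None)
        protocol = ProtocolConfig(
            preprocess=pre,
            manual_threshold=tuple(manual) if manual else None,
            **{k: v for k, v in proto.items()},
        )
        overrides = {str(k): tuple(v) for k, v in
                     d.get("manual_thresholds", {}).items()}
        return cls(protocol=protocol, manual_thresholds=overrides,
                   seed=int(d.get("seed", 0)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _override_key(meta: ImageMeta) -> str:
    return f"{meta.animal_id}|{meta.eye.value}|{meta.week}"


def read_threshold_overrides(path: str | Path) -> dict:
    """CSV with columns animal_id, eye, week, lo[, hi] -> override mapping."""
    df = pd.read_csv(path)
    needed = {"animal_id", "eye", "week", "lo"}
    if not needed.issubset(df.columns):
        raise ValueError(f"override CSV needs columns {sorted(needed)}")
    out = {}
    for row in df.itertuples(index=False):
        hi = getattr(row, "hi", float("inf"))
        if pd.isna(hi):
            hi = float("inf")
        out[f"{row.animal_id}|{row.eye}|{int(row.week)}"] = (float(row.lo),
                                                             float(hi))
    return out


def run_batch(manifest: str | Path | pd.DataFrame, config: RunConfig,
              image_root: str | Path | None = None
              ) -> tuple[pd.DataFrame, list[dict]]:
    """Run the two-stage protocol over every manifest row.

    Returns (cohort table, failures). Per-image failures are logged and
    skipped; the caller decides how to surface partial completion (the CLI
    exits 2 when failures is non-empty).
    """
    if isinstance(manifest, pd.DataFrame):
        metas = []
        for i, row in enumerate(manifest.itertuples(index=False)):
            metas.append(ImageMeta(animal_id=str(row.animal_id), eye=row.eye,
                                   week=int(row.week), group=row.group,
                                   source_path=str(row.source_path)))
        root = Path(image_root) if image_root else Path(".")
    else:
        metas = read_manifest(manifest)
        root = Path(image_root) if image_root else Path(manifest).parent
    if not metas:
        raise ValueError("empty manifest: nothing to process")

    chash = config.config_hash
    rows, failures = [], []
    for meta in metas:
        path = Path(meta.source_path)
        if not path.is_absolute():
            path = root / path
        try:
            img = read_image(path, meta=meta)
            cfg = config.protocol
            override = config.manual_thresholds.get(_override_key(meta))
            if override is not None:
                cfg = dataclasses.replace(cfg, manual_threshold=override)
            result = measure.run_protocol(img, cfg)
        except Exception as exc:  # per-image isolation is the contract
            log.warning("failed on %s: %s", meta.key, exc)
            failures.append({"key": meta.key, "path": str(path),
                             "error": str(exc)})
            continue
        s = result.summary
        rows.append({
            "animal_id": meta.animal_id, "eye": meta.eye.value,
            "week": meta.week, "group": meta.group.value,
            "cc": s.cc, "sua": s.sua_px, "mvi": s.mvi, "mcb": s.mcb,
            "ava": s.ava_px, "config_hash": chash,
            "image_sha256": hashlib.sha256(path.read_bytes()).hexdigest()[:12],
        })
    table = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return table, failures


def validate_counts(auto: pd.DataFrame, manual: pd.DataFrame) -> dict:
    """Regress automated cell counts against a manual gold standard.

    ``manual`` needs columns animal_id, eye, week, manual_cc. Rows are
    joined on the (animal_id, eye, week) key; disjoint keys are an error.
    """
    if "manual_cc" not in manual.columns:
        raise ValueError("manual table needs a manual_cc column")
    keys = ["animal_id", "eye", "week"]
    joined = auto.merge(manual[keys + ["manual_cc"]], on=keys, how="inner")
    if joined.empty:
        raise ValueError("no overlapping (animal_id, eye, week) keys")
    fit = score.fit_linear(joined["manual_cc"], joined["cc"])
    return {"slope": fit.slope, "intercept": fit.intercept,
            "r_squared": fit.r_squared, "p_value": fit.p_value, "n": fit.n}
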