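"""End-to-end pipeline configuration and runner.

:class:`PipelineConfig` is the file-level counterpart of the model
constructor: it names the band, window, estimator, region sets, test
direction, and the per-subject input manifest, and can be round-tripped
through YAML.  :func:`run_pipeline` reads every subject, fits
:class:`~parcelsync.model.InterSystemConnectivity`, and optionally writes
the results JSON, the strengths table, and the per-subject matrices.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .atlas import DEFAULT_CORE, DEFAULT_SENSORIMOTOR
from .errors import DegenerateInputError
from .io import read_recording, write_connectivity_csv
from .model import InterSystemConnectivity, StudyResults
from .network import ROISetPair

logger = logging.getLogger("parcelsync")


@dataclass(frozen=True)
class SubjectEntry:
    """One manifest row: where a subject's recording lives and its group."""

    path: str
    group: str
    subject_id: str | None = None
    format: str = "matrix"


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one study run."""

    manifest: tuple[SubjectEntry, ...]
    band: tuple[float, float] = (13.0, 30.0)
    window: tuple[float, float] = (0.0, 1.1)
    method: str = "ciplv"
    roi_sets: ROISetPair = field(
        default_factory=lambda: ROISetPair(
            sensorimotor=DEFAULT_SENSORIMOTOR, core=DEFAULT_CORE
        )
    )
    alpha: float = 0.05
    tail: str = "one_sided_less"
    group_order: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "manifest",
            tuple(
                SubjectEntry(**e) if isinstance(e, dict) else e for e in self.manifest
            ),
        )
        if not self.manifest:
            raise DegenerateInputError("empty manifest")
        groups = {e.group for e in self.manifest}
        if len(groups) != 2:
            raise DegenerateInputError(
                f"manifest must cover exactly 2 groups, got {sorted(groups)}"
            )

    def to_dict(self) -> dict:
        return {
            "band": list(self.band),
            "window": list(self.window),
            "method": self.method,
            "alpha": self.alpha,
            "tail": self.tail,
            "group_order": list(self.group_order) if self.group_order else None,
            "roi_sets": {
                "sensorimotor": list(self.roi_sets.sensorimotor),
                "core": list(self.roi_sets.core),
            },
            "manifest": [
                {
                    "path": e.path,
                    "group": e.group,
                    "subject_id": e.subject_id,
                    "format": e.format,
                }
                for e in self.manifest
            ],
        }

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        roi = raw.get("roi_sets") or {}
        return cls(
            manifest=tuple(SubjectEntry(**e) for e in raw["manifest"]),
            band=tuple(raw.get("band", (13.0, 30.0))),
            window=tuple(raw.get("window", (0.0, 1.1))),
            method=raw.get("method", "ciplv"),
            roi_sets=ROISetPair(
                sensorimotor=tuple(roi.get("sensorimotor", DEFAULT_SENSORIMOTOR)),
                core=tuple(roi.get("core", DEFAULT_CORE)),
            ),
            alpha=raw.get("alpha", 0.05),
            tail=raw.get("tail", "one_sided_less"),
            group_order=(
                tuple(raw["group_order"]) if raw.get("group_order") else None
            ),
        )


def build_model(config: PipelineConfig) -> InterSystemConnectivity:
    """Read every manifest entry and assemble the model."""
    recordings, groups, ids = [], [], []
    for i, entry in enumerate(config.manifest):
        logger.info("reading %s (%s, %s)", entry.path, entry.group, entry.format)
        recordings.append(read_recording(entry.path, format=entry.format))
        groups.append(entry.group)
        ids.append(entry.subject_id or f"sub-{i:02d}")
    return InterSystemConnectivity(
        recordings,
        groups,
        roi_sets=config.roi_sets,
        band=config.band,
        window=config.window,
        method=config.method,
        tail=config.tail,
        alpha=config.alpha,
        group_order=config.group_order,
        subject_ids=ids,
    )


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    keep_matrices: bool = False,
) -> StudyResults:
    """Read -> filter -> analytic -> window -> connectivity -> R -> w -> stats.

    When ``outdir`` is given, writes ``results.json``, ``strengths.csv``,
    and (with ``keep_matrices``) one square-CSV connectivity matrix per
    subject.
    """
    model = build_model(config)
    results = model.fit(keep_matrices=keep_matrices or outdir is not None)
    logger.info("comparison: %s", results.comparison)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = results.to_dict()
        payload["provenance"]["pipeline_config_hash"] = config.config_hash
        with open(outdir / "results.json", "w") as fh:
            json.dump(payload, fh, indent=1, default=list)
        results.strengths.to_csv(outdir / "strengths.csv", index=False)
        if results.matrices:
            for subject, m in results.matrices.items():
                write_connectivity_csv(m, outdir / f"{subject}_{m.method}.csv")
    return results
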