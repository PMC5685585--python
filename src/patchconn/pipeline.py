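"""Full-workflow driver: grid -> connectivity -> MDMR per group pair ->
overlap, projection, strength, and MDS stages, with a run manifest.

The matrices-only entry point is first-class: supplying precomputed
connectivity matrices skips the imaging stages entirely.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from patchconn import __version__
from patchconn.analysis import (
    compare_projection,
    compare_strength,
    group_mean_connectome,
    groups_mds,
    overlap_report,
    projection_scores,
    strengths_by_group,
)
from patchconn.errors import PatchconnError, ValidationError
from patchconn.mdmr import run_mdmr
from patchconn.network import build_patch_grid, compute_connectivity
from patchconn import io as pio

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (JSON or YAML on disk)."""

    labels_path: str
    out_dir: str
    matrices_dir: str | None = None
    volumes_dir: str | None = None
    mask_path: str | None = None
    patch_dims: tuple = (10, 15, 20)
    retention_threshold: float = 0.5
    kind: str = "pearson"
    n_perm: int = 9999
    alpha: float = 0.01
    family_size: int | None = None  # Bonferroni family; default = grid N
    seed: int = 0
    comparisons: list | None = None  # [[groupA, groupB], ...]; default all pairs
    reference_group: str | None = None  # default: first group in the labels
    projection_pair: list | None = None  # default: first comparison without ref
    mds_nodes: list | None = None  # default: nodes significant in all comparisons
    n_jobs: int = 1

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            yaml.safe_load(text)
            if path.suffix in (".yml", ".yaml")
            else json.loads(text)
        )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not Path(self.labels_path).exists():
            raise ValidationError(f"labels file not found: {self.labels_path}")
        if self.matrices_dir is None and self.volumes_dir is None:
            raise ValidationError("need either matrices_dir or volumes_dir")
        if self.matrices_dir is None:
            if self.mask_path is None:
                raise ValidationError("volumes input requires mask_path")
            for p in (self.volumes_dir, self.mask_path):
                if not Path(p).exists():
                    raise ValidationError(f"path not found: {p}")
        elif not Path(self.matrices_dir).exists():
            raise ValidationError(f"path not found: {self.matrices_dir}")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured workflow; returns (and writes) the manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.__dict__.items()},
        "version": __version__,
        "started": datetime.now(timezone.utc).isoformat(),
        "outputs": {},
        "warnings": [],
        "status": "running",
    }
    stage = "setup"
    try:
        stage = "labels"
        labels_df = pio.read_labels(config.labels_path)
        groups_in_order = list(dict.fromkeys(labels_df["group"]))

        comparisons = config.comparisons or [
            list(pair) for pair in combinations(groups_in_order, 2)
        ]
        for a, b in comparisons:
            for g in (a, b):
                if g not in groups_in_order:
                    raise ValidationError(
                        f"comparison group {g!r} not present in labels"
                    )
        reference = config.reference_group or groups_in_order[0]
        if reference not in groups_in_order:
            raise ValidationError(f"reference group {reference!r} not in labels")

        stage = "connectivity"
        subject_ids = labels_df["subject_id"].tolist()
        subject_labels = labels_df["group"].tolist()
        if config.matrices_dir is not None:
            matrices = pio.read_matrices_dir(config.matrices_dir, subject_ids)
            stack = np.stack([m.values for m in matrices])
            for m in matrices:
                if m.flagged_nodes:
                    manifest["warnings"].append(
                        f"subject {m.subject_id}: zero-variance node(s) "
                        f"{list(m.flagged_nodes)}"
                    )
        else:
            mask = pio.read_volume(config.mask_path) > 0.5
            grid = build_patch_grid(
                mask, tuple(config.patch_dims), config.retention_threshold
            )
            grid_path = pio.write_grid(grid, out_dir / "grid.json")
            manifest["outputs"]["grid"] = str(grid_path)
            vol_dir = Path(config.volumes_dir)
            mat_dir = out_dir / "matrices"
            stack_list = []
            for sid in subject_ids:
                candidates = [vol_dir / f"{sid}.nii.gz", vol_dir / f"{sid}.nii"]
                vol_path = next((c for c in candidates if c.exists()), None)
                if vol_path is None:
                    raise ValidationError(f"no volume file for subject {sid}")
                conn = compute_connectivity(
                    pio.read_volume(vol_path), grid, subject_id=sid
                )
                if conn.flagged_nodes:
                    manifest["warnings"].append(
                        f"subject {sid}: zero-variance node(s) "
                        f"{list(conn.flagged_nodes)}"
                    )
                pio.write_matrix(conn, mat_dir / f"{sid}.tsv.gz")
                stack_list.append(conn.values)
            stack = np.stack(stack_list)
            manifest["outputs"]["matrices"] = str(mat_dir)
        n_nodes = stack.shape[1]
        family = config.family_size or n_nodes
        label_arr = np.asarray(subject_labels)

        stage = "mdmr"
        significant_sets: dict = {}
        seed_seq = np.random.SeedSequence(config.seed)
        comp_seeds = seed_seq.spawn(len(comparisons))
        for (a, b), comp_seed in zip(comparisons, comp_seeds):
            sel = np.isin(label_arr, [a, b])
            logger.info("MDMR %s vs %s (%d subjects, %d nodes)",
                        a, b, int(sel.sum()), n_nodes)
            result = run_mdmr(
                stack[sel], label_arr[sel].tolist(), kind=config.kind,
                n_perm=config.n_perm, alpha=config.alpha,
                seed=comp_seed, n_jobs=config.n_jobs,
            )
            name = f"{a}_vs_{b}"
            path = out_dir / f"mdmr_{name}.csv"
            result.table.to_csv(path, index=False)
            manifest["outputs"][f"mdmr_{name}"] = str(path)
            significant_sets[name] = result.significant_nodes

        stage = "overlap"
        report = overlap_report(significant_sets)
        overlap_path = out_dir / "overlap.json"
        overlap_path.write_text(json.dumps(report, indent=1))
        manifest["outputs"]["overlap"] = str(overlap_path)

        stage = "projection"
        ref_mean = group_mean_connectome(stack[label_arr == reference])
        proj_pair = config.projection_pair or next(
            (pair for pair in comparisons if reference not in pair), None
        )
        if proj_pair is not None:
            a, b = proj_pair
            scores_a = np.stack([
                projection_scores(stack[label_arr == a], ref_mean, i)
                for i in range(n_nodes)
            ])
            scores_b = np.stack([
                projection_scores(stack[label_arr == b], ref_mean, i)
                for i in range(n_nodes)
            ])
            proj = compare_projection(scores_a, scores_b, family, config.alpha)
            path = out_dir / f"projection_{a}_vs_{b}.csv"
            proj.to_csv(path, index=False)
            manifest["outputs"]["projection"] = str(path)

        stage = "strength"
        strengths = strengths_by_group(stack, subject_labels)
        strength_table = compare_strength(strengths, reference)
        path = out_dir / "strength.csv"
        strength_table.to_csv(path, index=False)
        manifest["outputs"]["strength"] = str(path)

        stage = "mds"
        mean_by_group = {
            g: group_mean_connectome(stack[label_arr == g])
            for g in groups_in_order
        }
        if config.mds_nodes is not None:
            subset = sorted(int(i) for i in config.mds_nodes)
        else:
            nonempty = [s for s in significant_sets.values() if s]
            subset = sorted(set.intersection(*nonempty)) if nonempty else []
        if len(groups_in_order) >= 2:
            coords_all, strain_all = groups_mds(mean_by_group, node_subset=None)
            coords_all.to_csv(out_dir / "mds_all_nodes.csv", index=False)
            manifest["outputs"]["mds_all_nodes"] = str(out_dir / "mds_all_nodes.csv")
            manifest["mds_all_nodes_strain"] = strain_all
            if subset:
                coords_sub, strain_sub = groups_mds(
                    mean_by_group, node_subset=subset
                )
                coords_sub.to_csv(out_dir / "mds_significant_nodes.csv",
                                  index=False)
                manifest["outputs"]["mds_significant_nodes"] = str(
                    out_dir / "mds_significant_nodes.csv"
                )
                manifest["mds_node_subset"] = subset
                manifest["mds_significant_nodes_strain"] = strain_sub

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest["finished"] = datetime.now(timezone.utc).isoformat()
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PatchconnError(f"stage {stage!r} failed: {exc}") from exc

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    manifest["hashes"] = {
        name: _sha256(Path(p))
        for name, p in manifest["outputs"].items()
        if Path(p).is_file()
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
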