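"""Scoring detections against simulator ground truth.

Five statistics summarize a run: localization RMSE over paired events,
missed and spurious percentages, and the minimum / maximum pair
deviation.  Pairing is per frame, one-to-one, greedy on globally
increasing distance within a vicinity radius (default 385 um, the
merged-event scale: beyond it two echoes are distinct events by
construction).  Greedy closest-first is deterministic and near-optimal
at these sparsities; the exhaustive minimum-total-distance assignment is
kept as a test oracle, not used here.

Ground truth is merged-aware.  In ``merged`` mode the ground-truth
events are the merged-event centers — the intensity-weighted mean of the
member particle positions, weighted by their rendered peak intensities,
which is what the localizer estimates for an unresolved clump.  In
``single`` mode they are the well-separated particles (singleton merge
labels); multi-particle clumps are then deliberately not scored, since
no algorithm output is defined for them in that mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reporting import merge_threshold_um
from .segmentation import DetectionEvent
from .simulate.echoes import EchoAppearance
from .simulate.particles import GroundTruthRecord

__all__ = ["EvaluationReport", "ground_truth_events", "pair_events",
           "compute_rmse", "evaluate_run"]

DEFAULT_PAIRING_RADIUS_UM = merge_threshold_um()   # 385 um


@dataclass
class EvaluationReport:
    """Detection / localization accuracy of one run."""

    n_ground_truth: int
    n_detected: int
    n_pairs: int
    rmse_um: float                      # nan when no pairs
    missed_pct: float
    spurious_pct: float
    min_dev_um: float
    max_dev_um: float
    pairs: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in self.__dict__.items() if k != "pairs"}


def ground_truth_events(records: list[GroundTruthRecord],
                        appearances: dict[int, EchoAppearance] | None = None,
                        mode: str = "merged") -> pd.DataFrame:
    """Ground-truth events to score against, one row per event.

    Columns: frame, x_um, y_um, n_particles.  See the module docstring
    for the single / merged semantics.
    """
    if mode not in {"single", "merged"}:
        raise ValueError(f"unknown evaluation mode {mode!r}")
    rows = []
    for rec in records:
        for lab, idx in rec.groups().items():
            if mode == "single" and len(idx) != 1:
                continue
            xy = rec.xy_um[idx]
            if appearances is not None:
                w = np.array([appearances[int(rec.particle_ids[i])].peak_intensity
                              for i in idx])
            else:
                w = np.ones(len(idx))
            cx, cy = (xy * w[:, None]).sum(axis=0) / w.sum()
            rows.append((rec.frame_index, float(cx), float(cy), len(idx)))
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "n_particles"])


def _greedy_pairs(gt_xy: np.ndarray, det_xy: np.ndarray,
                  radius_um: float) -> list[tuple[int, int, float]]:
    """One-to-one greedy matching on globally increasing distance."""
    if len(gt_xy) == 0 or len(det_xy) == 0:
        return []
    d = np.hypot(gt_xy[:, None, 0] - det_xy[None, :, 0],
                 gt_xy[:, None, 1] - det_xy[None, :, 1])
    gi, dj = np.nonzero(d <= radius_um)
    order = np.argsort(d[gi, dj], kind="stable")
    used_g: set[int] = set()
    used_d: set[int] = set()
    out = []
    for k in order:
        g, j = int(gi[k]), int(dj[k])
        if g in used_g or j in used_d:
            continue
        used_g.add(g)
        used_d.add(j)
        out.append((g, j, float(d[g, j])))
    return out


def pair_events(ground_truth: pd.DataFrame,
                detections: list[DetectionEvent] | pd.DataFrame,
                pairing_radius_um: float = DEFAULT_PAIRING_RADIUS_UM
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pair ground-truth events with detections, frame by frame.

    Returns (pairs, missed ground truth, spurious detections); pairs has
    columns frame, gt_index, det_index, deviation_um where the indices
    refer to rows of the two input tables.
    """
    if isinstance(detections, list):
        det = pd.DataFrame(
            [(e.frame_index, e.centroid_x_um, e.centroid_y_um)
             for e in detections], columns=["frame", "x_um", "y_um"])
    else:
        det = detections[["frame", "x_um", "y_um"]].copy()
    det = det.reset_index(drop=True)
    gt = ground_truth.reset_index(drop=True)

    pair_rows = []
    missed_idx: list[int] = []
    spurious_idx: list[int] = []
    frames = sorted(set(gt["frame"]).union(det["frame"]))
    for f in frames:
        g_idx = gt.index[gt["frame"] == f].to_numpy()
        d_idx = det.index[det["frame"] == f].to_numpy()
        g_xy = gt.loc[g_idx, ["x_um", "y_um"]].to_numpy()
        d_xy = det.loc[d_idx, ["x_um", "y_um"]].to_numpy()
        matches = _greedy_pairs(g_xy, d_xy, pairing_radius_um)
        mg = {m[0] for m in matches}
        md = {m[1] for m in matches}
        for g, j, dev in matches:
            pair_rows.append((f, int(g_idx[g]), int(d_idx[j]), dev))
        missed_idx.extend(int(i) for k, i in enumerate(g_idx) if k not in mg)
        spurious_idx.extend(int(i) for k, i in enumerate(d_idx) if k not in md)

    pairs = pd.DataFrame(pair_rows,
                         columns=["frame", "gt_index", "det_index",
                                  "deviation_um"])
    return pairs, gt.loc[missed_idx], det.loc[spurious_idx]


def compute_rmse(pairs: pd.DataFrame) -> float:
    """Root mean square of the pair deviations; nan for zero pairs."""
    if len(pairs) == 0:
        return float("nan")
    return float(np.sqrt(np.mean(pairs["deviation_um"].to_numpy() ** 2)))


def evaluate_run(records: list[GroundTruthRecord],
                 detections: list[DetectionEvent],
                 appearances: dict[int, EchoAppearance] | None = None,
                 mode: str = "merged",
                 pairing_radius_um: float = DEFAULT_PAIRING_RADIUS_UM
                 ) -> EvaluationReport:
    """Full accuracy report for one detection run against ground truth."""
    gt = ground_truth_events(records, appearances, mode)
    pairs, missed, spurious = pair_events(gt, detections, pairing_radius_um)
    n_gt, n_det, n_pairs = len(gt), len(detections), len(pairs)
    dev = pairs["deviation_um"].to_numpy()
    return EvaluationReport(
        n_ground_truth=n_gt,
        n_detected=n_det,
        n_pairs=n_pairs,
        rmse_um=compute_rmse(pairs),
        missed_pct=100.0 * (n_gt - n_pairs) / n_gt if n_gt else float("nan"),
        spurious_pct=100.0 * (n_det - n_pairs) / n_det if n_det else float("nan"),
        min_dev_um=float(dev.min()) if n_pairs else float("nan"),
        max_dev_um=float(dev.max()) if n_pairs else float("nan"),
        pairs=pairs,
    )
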