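"""Metrics, post-processing, and reporting.

Dice overlap and (95th-percentile or plain) Hausdorff distance per class,
the hole-filling / small-component post-processing applied before the
"Post" columns of result tables, and tabular report assembly.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "dice",
    "hausdorff",
    "postprocess",
    "evaluate_prediction",
    "MetricReport",
    "report",
]


def dice(pred, ref, c):
    """Dice overlap 2|A∩B|/(|A|+|B|) for class ``c``; empty-empty -> 1."""
    a = np.asarray(pred) == c
    b = np.asarray(ref) == c
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _boundary(mask):
    """Voxel coordinates of the mask's inner boundary."""
    eroded = ndimage.binary_erosion(mask)
    return np.argwhere(mask & ~eroded)


def hausdorff(pred, ref, c, percentile=None, sentinel=None):
    """Symmetric Hausdorff boundary distance for class ``c`` in voxel units.

    ``percentile=95`` gives the robust HD95 variant.  If either mask is
    empty the configured sentinel (default: image diagonal) is returned.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    a = _boundary(pred == c)
    b = _boundary(ref == c)
    if len(a) == 0 or len(b) == 0:
        if sentinel is None:
            sentinel = float(np.linalg.norm(pred.shape))
        return sentinel
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    if percentile is None:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile),
                     np.percentile(d_ba, percentile)))


def _structures(ndim):
    # components: full connectivity (8 / 26); holes: minimal (4 / 6)
    return (ndimage.generate_binary_structure(ndim, ndim),
            ndimage.generate_binary_structure(ndim, 1))


def postprocess(pred, min_size=4):
    """Fill enclosed holes and drop small connected components, per class.

    Component removal uses full (8/26) connectivity, hole filling minimal
    (4/6) connectivity.  Idempotent.
    """
    pred = np.asarray(pred)
    out = np.zeros_like(pred)
    comp_struct, hole_struct = _structures(pred.ndim)
    for c in np.unique(pred):
        if c == 0:
            continue
        mask = pred == c
        mask = ndimage.binary_fill_holes(mask, structure=hole_struct)
        labeled, n = ndimage.label(mask, structure=comp_struct)
        if n:
            sizes = ndimage.sum_labels(np.ones_like(labeled), labeled,
                                       index=np.arange(1, n + 1))
            keep = np.flatnonzero(sizes >= min_size) + 1
            mask = np.isin(labeled, keep)
        out[mask & (out == 0)] = c
    return out


def evaluate_prediction(pred, ref, classes, hd_percentile=95):
    """Per-class Dice and HD for one (prediction, reference) pair."""
    return {
        c: {"dice": dice(pred, ref, c),
            "hd": hausdorff(pred, ref, c, percentile=hd_percentile)}
        for c in classes
    }


class MetricReport:
    """Per-client, per-class Dice/HD table with pre/post variants."""

    def __init__(self, rows):
        self.frame = pd.DataFrame(
            rows, columns=["client", "class", "variant", "dice", "hd"]
        )

    def client_means(self, variant="pre"):
        sub = self.frame[self.frame["variant"] == variant]
        return sub.groupby("client")[["dice", "hd"]].mean()

    def overall_mean(self, variant="pre"):
        return self.client_means(variant).mean()

    def to_table(self):
        """Wide per-client table with a trailing Mean row, one per variant."""
        out = {}
        for variant in self.frame["variant"].unique():
            cm = self.client_means(variant)
            table = cm.copy()
            table.loc["mean"] = cm.mean()
            out[variant] = table
        return out

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            variant: {str(k): {"dice": float(v["dice"]), "hd": float(v["hd"])}
                      for k, v in table.iterrows()}
            for variant, table in self.to_table().items()
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2)
        return payload

    def __str__(self):
        lines = []
        for variant, table in self.to_table().items():
            lines.append(f"[{variant}]")
            lines.append(table.to_string(float_format=lambda x: f"{x:.4f}"))
        return "\n".join(lines)


def report(predictions, references, classes, client_ids=None, min_size=4,
           hd_percentile=95):
    """Assemble a :class:`MetricReport` over clients.

    ``predictions``/``references`` are per-client lists of label maps; both
    raw ("pre") and post-processed ("post") variants are scored.
    """
    if client_ids is None:
        client_ids = list(range(1, len(predictions) + 1))
    rows = []
    for cid, preds, refs in zip(client_ids, predictions, references):
        for pred, ref in zip(preds, refs):
            for variant, p in (("pre", pred), ("post", postprocess(pred, min_size))):
                scores = evaluate_prediction(p, ref, classes, hd_percentile)
                for c, s in scores.items():
                    rows.append((cid, c, variant, s["dice"], s["hd"]))
    return MetricReport(rows)
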