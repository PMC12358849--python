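"""High-order domain segmentation, tracking, and the homogeneous null.

Tissue-scale nematic order emerges by growth and fusion of high-order
domains: connected regions where the local order parameter exceeds a
threshold.  This module segments those domains per frame, measures
their number and equivalent-circle diameter, links them across frames
by pixel overlap to detect fusion events, and builds the counterfactual
in which the order-parameter field rises *homogeneously* in space while
matching the observed spatial-mean trajectory — if real domains grow by
localized ordering, their diameters exceed the null's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .nematic import OrderField
from .orientation import Mask

__all__ = [
    "DomainLabelMap",
    "DomainTrack",
    "NullModelResult",
    "high_order_domains",
    "domain_metrics",
    "track_domains",
    "homogeneous_null",
]

EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class DomainLabelMap:
    """8-connected components of {S ≥ threshold} ∩ mask, by decreasing area."""

    labels: np.ndarray  # 0 = background / disordered
    threshold_used: float
    min_area_px: int
    pixel_size_um: float

    @property
    def n_domains(self) -> int:
        return int(self.labels.max())

    def areas_px(self) -> np.ndarray:
        n = self.n_domains
        if n == 0:
            return np.zeros(0, dtype=int)
        return ndimage.sum_labels(
            np.ones_like(self.labels), self.labels, index=np.arange(1, n + 1)
        ).astype(int)


@dataclass
class DomainTrack:
    """Per-frame lineage (child label → parent labels) and events."""

    lineage: list[dict[int, set[int]]]  # entry t maps frame t+1 children to frame t parents
    events: list[tuple[int, str, tuple[int, ...]]]  # (frame, type, labels)


@dataclass
class NullModelResult:
    """Homogeneous-increase counterfactual fields and domain metrics."""

    null_fields: list[OrderField]
    null_maps: list[DomainLabelMap]
    comparison: pd.DataFrame  # frame, observed/null mean diameter, means


def high_order_domains(
    field: OrderField,
    mask: Mask,
    threshold: float = 0.6,
    min_area_px: int = 25,
) -> DomainLabelMap:
    """Segment high-order domains: S ≥ threshold, 8-connected, area-filtered."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    binary = np.zeros(field.S.shape, dtype=bool)
    defined = field.defined & mask.inside
    binary[defined] = field.S[defined] >= threshold
    raw, n = ndimage.label(binary, structure=EIGHT)
    if n == 0:
        return DomainLabelMap(raw, threshold, min_area_px, field.pixel_size_um)
    areas = ndimage.sum_labels(np.ones_like(raw), raw, index=np.arange(1, n + 1))
    keep = np.nonzero(areas >= min_area_px)[0] + 1
    order = keep[np.argsort(-areas[keep - 1], kind="stable")]
    remap = np.zeros(n + 1, dtype=int)
    remap[order] = np.arange(1, len(order) + 1)
    labels = remap[raw]
    return DomainLabelMap(labels, threshold, min_area_px, field.pixel_size_um)


def domain_metrics(
    label_map: DomainLabelMap, mask: Mask | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-domain table and frame summary.

    Equivalent diameter is the circle-equivalent 2·px·sqrt(area/π).
    An empty frame reports mean diameter as NaN (missing), not 0.
    """
    px = label_map.pixel_size_um
    areas = label_map.areas_px()
    diam = 2.0 * px * np.sqrt(areas / np.pi)
    table = pd.DataFrame(
        {
            "label": np.arange(1, len(areas) + 1),
            "area_px": areas,
            "area_um2": areas * px**2,
            "equivalent_diameter_um": diam,
        }
    )
    mask_area = int(mask.area_px) if mask is not None else label_map.labels.size
    summary = {
        "n_domains": int(len(areas)),
        "mean_diameter_um": float(diam.mean()) if len(diam) else float("nan"),
        "total_high_order_fraction": float(areas.sum() / mask_area) if mask_area else 0.0,
    }
    return table, summary


def _overlap_links(
    parents: np.ndarray, children: np.ndarray, min_overlap_frac: float
) -> dict[int, set[int]]:
    """child label → {parent labels} by relative overlap.

    A link exists when the intersection covers at least
    ``min_overlap_frac`` of the parent *or* of the child (the symmetric
    rule makes fusion and split detection mirror images: fused parents
    are largely inside the child, split children largely inside the
    parent).
    """
    n_p, n_c = int(parents.max()), int(children.max())
    links: dict[int, set[int]] = {c: set() for c in range(1, n_c + 1)}
    if n_p == 0 or n_c == 0:
        return links
    joint = np.bincount(
        (parents * (n_c + 1) + children).ravel(),
        minlength=(n_p + 1) * (n_c + 1),
    ).reshape(n_p + 1, n_c + 1)
    parent_area = joint.sum(axis=1)
    child_area = joint.sum(axis=0)
    for p in range(1, n_p + 1):
        if parent_area[p] == 0:
            continue
        for c in range(1, n_c + 1):
            if child_area[c] == 0:
                continue
            frac = max(joint[p, c] / parent_area[p], joint[p, c] / child_area[c])
            if frac >= min_overlap_frac:
                links[c].add(p)
    return links


def track_domains(
    maps: list[DomainLabelMap], min_overlap_frac: float = 0.3
) -> DomainTrack:
    """Link domains across frames by overlap; detect fusion/split/birth/death.

    A fusion at frame t+1 has ≥ 2 parents from frame t linked to one
    child; a split is symmetric; unlinked children are births, unlinked
    parents deaths.  No registration is applied between frames.
    """
    if len(maps) < 2:
        raise ValueError("tracking needs at least 2 frames")
    shapes = {m.labels.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("all frames must share one shape")
    lineage: list[dict[int, set[int]]] = []
    events: list[tuple[int, str, tuple[int, ...]]] = []
    for t in range(len(maps) - 1):
        parents, children = maps[t].labels, maps[t + 1].labels
        links = _overlap_links(parents, children, min_overlap_frac)
        lineage.append(links)
        linked_parents: set[int] = set()
        for c, ps in sorted(links.items()):
            linked_parents |= ps
            if len(ps) >= 2:
                events.append((t + 1, "fusion", tuple(sorted(ps)) + (c,)))
            elif len(ps) == 0:
                events.append((t + 1, "birth", (c,)))
        child_count: dict[int, int] = {}
        for c, ps in links.items():
            for p in ps:
                child_count[p] = child_count.get(p, 0) + 1
        for p in range(1, int(parents.max()) + 1):
            if child_count.get(p, 0) >= 2:
                kids = tuple(sorted(c for c, ps in links.items() if p in ps))
                events.append((t + 1, "split", (p,) + kids))
            if p not in linked_parents:
                events.append((t + 1, "death", (p,)))
    return DomainTrack(lineage=lineage, events=events)


def fusion_frames(track: DomainTrack) -> list[int]:
    return sorted(frame for frame, kind, _ in track.events if kind == "fusion")


def homogeneous_null(
    initial_field: OrderField,
    observed_mean_trajectory: np.ndarray,
    mask: Mask,
    threshold: float = 0.6,
    min_area_px: int = 25,
    mode: str = "additive",
    observed_mean_diameter_um: np.ndarray | None = None,
) -> NullModelResult:
    """Homogeneous-increase null model of domain growth.

    For each time t the null order field raises the *initial* spatial
    pattern uniformly so its mean matches the observed mean m(t):
    additive S₀ + (m(t) − m(0)) clipped to [0, 1] (multiplicative
    S₀·m(t)/m(0) behind ``mode``).  The same domain pipeline is applied
    and mean domain diameters tabulated against the observations.
    """
    m = np.asarray(observed_mean_trajectory, dtype=float)
    sel = initial_field.defined & mask.inside
    if not sel.any():
        raise ValueError("initial field undefined inside the mask")
    m0 = float(initial_field.S[sel].mean())
    if abs(m[0] - m0) > 1e-6:
        raise ValueError("trajectory must start at the initial field's mean")
    fields, maps_, rows = [], [], []
    for t, mt in enumerate(m):
        S = np.full(initial_field.S.shape, np.nan)
        if mode == "additive":
            S[sel] = np.clip(initial_field.S[sel] + (mt - m0), 0.0, 1.0)
        elif mode == "multiplicative":
            if m0 <= 0:
                raise ValueError("multiplicative mode needs a positive initial mean")
            S[sel] = np.clip(initial_field.S[sel] * (mt / m0), 0.0, 1.0)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        fld = OrderField(S=S, window_um=initial_field.window_um,
                         pixel_size_um=initial_field.pixel_size_um)
        lm = high_order_domains(fld, mask, threshold, min_area_px)
        _, summary = domain_metrics(lm, mask)
        fields.append(fld)
        maps_.append(lm)
        rows.append(
            {
                "frame": t,
                "target_mean": mt,
                "null_mean_postclip": float(S[sel].mean()),
                "null_n_domains": summary["n_domains"],
                "null_mean_diameter_um": summary["mean_diameter_um"],
                "observed_mean_diameter_um": (
                    float(observed_mean_diameter_um[t])
                    if observed_mean_diameter_um is not None
                    else np.nan
                ),
            }
        )
    return NullModelResult(
        null_fields=fields, null_maps=maps_, comparison=pd.DataFrame(rows)
    )
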