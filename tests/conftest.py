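"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from qwaseg import LabelMap, WoodTypeConfig, generate_scene

WOOD_TYPES = ("conifer", "diffuse", "semidiffuse", "ringporous")


def scene_for(seed: int, wood_type: str | None = None, **kw):
    """One deterministic synthetic scene; wood type cycles with the seed."""
    wt = wood_type or WOOD_TYPES[seed % len(WOOD_TYPES)]
    return generate_scene(getattr(WoodTypeConfig, wt)(seed=seed, **kw))


@pytest.fixture(scope="session")
def conifer_scene():
    return scene_for(0, "conifer")


@pytest.fixture(scope="session")
def diffuse_scene():
    return scene_for(1, "diffuse")


def random_rect_labelmap(rng: np.random.Generator, shape=(64, 64),
                         max_instances: int = 8, margin: int = 2) -> LabelMap:
    """Up to ``max_instances`` non-overlapping interior rectangles."""
    h, w = shape
    labels = np.zeros(shape, dtype=np.int32)
    n = int(rng.integers(1, max_instances + 1))
    next_id = 1
    for _ in range(n):
        for _try in range(50):
            rh = int(rng.integers(4, 14))
            rw = int(rng.integers(4, 14))
            r0 = int(rng.integers(margin, h - rh - margin))
            c0 = int(rng.integers(margin, w - rw - margin))
            region = labels[max(0, r0 - 1):r0 + rh + 1, max(0, c0 - 1):c0 + rw + 1]
            if (region == 0).all():
                labels[r0:r0 + rh, c0:c0 + rw] = next_id
                next_id += 1
                break
    return LabelMap(labels)


def jittered_prediction(rng: np.random.Generator, gt: LabelMap,
                        max_shift: int = 4) -> LabelMap:
    """A prediction that shifts, drops or invents instances so that candidate
    IoUs scatter around the matching threshold."""
    labels = gt.labels
    h, w = labels.shape
    pred = np.zeros_like(labels)
    next_id = 1
    for i in range(1, gt.n_instances + 1):
        u = rng.random()
        if u < 0.15:
            continue  # dropped
        dr = int(rng.integers(-max_shift, max_shift + 1))
        dc = int(rng.integers(-max_shift, max_shift + 1))
        rs, cs = np.nonzero(labels == i)
        rs = np.clip(rs + dr, 0, h - 1)
        cs = np.clip(cs + dc, 0, w - 1)
        keep = pred[rs, cs] == 0
        if keep.any():
            pred[rs[keep], cs[keep]] = next_id
            next_id += 1
    for _ in range(int(rng.integers(0, 3))):  # invented blobs
        rh, rw = int(rng.integers(3, 8)), int(rng.integers(3, 8))
        r0 = int(rng.integers(1, h - rh - 1))
        c0 = int(rng.integers(1, w - rw - 1))
        region = pred[r0:r0 + rh, c0:c0 + rw]
        if (region == 0).all():
            pred[r0:r0 + rh, c0:c0 + rw] = next_id
            next_id += 1
    return LabelMap(pred)


def exhaustive_best_assignment(candidates):
    """Brute-force one-to-one assignment maximising (match count, total IoU)
    over candidate (iou, gt_id, pred_id) edges — the matcher's oracle."""
    best = {"count": 0, "iou": 0.0, "pairs": frozenset()}

    def recurse(i, used_g, used_p, count, total, chosen):
        if i == len(candidates):
            if (count, total) > (best["count"], best["iou"]):
                best.update(count=count, iou=total, pairs=frozenset(chosen))
            return
        recurse(i + 1, used_g, used_p, count, total, chosen)
        iou, g, p = candidates[i]
        if g not in used_g and p not in used_p:
            recurse(i + 1, used_g | {g}, used_p | {p},
                    count + 1, total + iou, chosen | {(g, p)})

    recurse(0, frozenset(), frozenset(), 0, 0.0, set())
    return best["pairs"]
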