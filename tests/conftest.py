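"""Shared fixtures: small phantoms, random tensor pairs, and independent
brute-force oracles used to cross-check the vectorized implementations."""

from __future__ import annotations

import math

import numpy as np
import pytest

from patchbalance import (
    OrganSpec,
    PhantomConfig,
    generate_phantom,
    han_like_preset,
    phantom_dataset,
)

# ---------------------------------------------------------------------------
# independent loss oracles: plain triple loops over (b, c, v), no shared code
# with patchbalance.losses


def loop_cross_entropy(P, G, normalization="per_voxel", clamp=1e-12):
    B, C, V = P.shape
    total = 0.0
    for b in range(B):
        for c in range(C):
            for v in range(V):
                if G[b, c, v]:
                    total -= G[b, c, v] * math.log(max(P[b, c, v], clamp))
    return total / (B * V if normalization == "per_voxel" else B)


def loop_multiclass_dice(P, G, eps=1e-5):
    B, C, V = P.shape
    acc = 0.0
    for b in range(B):
        for c in range(C):
            inter = sum(P[b, c, v] * G[b, c, v] for v in range(V))
            psum = sum(P[b, c, v] for v in range(V))
            gsum = sum(G[b, c, v] for v in range(V))
            acc += (2 * inter + eps) / (psum + gsum + eps)
    return acc / (B * C)


def loop_nnu_dice(P, G, eps=1e-5):
    B, C, V = P.shape
    acc = 0.0
    for c in range(1, C):
        inter = sum(P[b, c, v] * G[b, c, v] for b in range(B) for v in range(V))
        psum = sum(P[b, c, v] for b in range(B) for v in range(V))
        gsum = sum(G[b, c, v] for b in range(B) for v in range(V))
        acc += (2 * inter + eps) / (psum + gsum + eps)
    return acc / (C - 1)


def loop_ca_dice(P, G, eps=1e-5, include_background=False):
    B, C, V = P.shape
    acc, n = 0.0, 0
    for b in range(B):
        for c in range(C):
            if c == 0 and not include_background:
                continue
            gsum = sum(G[b, c, v] for v in range(V))
            if gsum == 0:
                continue
            inter = sum(P[b, c, v] * G[b, c, v] for v in range(V))
            psum = sum(P[b, c, v] for v in range(V))
            acc += 2 * inter / (psum + gsum + eps)
            n += 1
    return (acc / n if n else math.nan), n


def random_tensor_pair(rng, B, C, V):
    """A softmax-normalized P and a one-hot G of matching shape."""
    logits = rng.normal(size=(B, C, V))
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    P = e / e.sum(axis=1, keepdims=True)
    labels = rng.integers(0, C, size=(B, V))
    G = np.zeros((B, C, V))
    for b in range(B):
        G[b, labels[b], np.arange(V)] = 1.0
    return P, G


# ---------------------------------------------------------------------------
# brute-force surface-distance oracles


def brute_surface_voxels(mask):
    """Mask voxels with a 6-neighbour outside the mask (border = outside)."""
    mask = np.asarray(mask).astype(bool)
    out = np.zeros_like(mask)
    nx, ny, nz = mask.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
                    px, py, pz = x + dx, y + dy, z + dz
                    if not (0 <= px < nx and 0 <= py < ny and 0 <= pz < nz):
                        out[x, y, z] = True
                        break
                    if not mask[px, py, pz]:
                        out[x, y, z] = True
                        break
    return out


def brute_directed_distances(src_mask, dst_mask, spacing):
    """All-pairs nearest surface-to-surface distances in mm, src -> dst."""
    sp = np.asarray(spacing, dtype=float)
    src = np.argwhere(brute_surface_voxels(src_mask)) * sp
    dst = np.argwhere(brute_surface_voxels(dst_mask)) * sp
    return np.array([min(np.linalg.norm(s - d) for d in dst) for s in src])


def brute_hausdorff(A, B, spacing, percentile=95.0):
    pooled = np.concatenate(
        [brute_directed_distances(A, B, spacing), brute_directed_distances(B, A, spacing)]
    )
    return float(np.percentile(pooled, percentile, method="linear"))


def brute_surface_dice(A, B, spacing, tau):
    d_ab = brute_directed_distances(A, B, spacing)
    d_ba = brute_directed_distances(B, A, spacing)
    return (int((d_ab <= tau).sum()) + int((d_ba <= tau).sum())) / (len(d_ab) + len(d_ba))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_phantom():
    """One 64x64x32 preset phantom, all 8 classes present."""
    return generate_phantom(han_like_preset("small", seed=11))


@pytest.fixture(scope="session")
def default_phantom():
    """One 128x128x64 preset phantom with the documented imbalance."""
    return generate_phantom(han_like_preset("default", seed=11))


@pytest.fixture(scope="session")
def phantom_set():
    """Three default-scale phantoms with distinct noise seeds."""
    return phantom_dataset(3, "default", seed=7)


def cube_phantom_config(seed: int = 0) -> PhantomConfig:
    """A 48x48x48 seven-organ phantom for the training demo."""
    organs = (
        OrganSpec(1, "brainstem", "ellipsoid", (24, 30, 24), (5, 6, 7), 40.0),
        OrganSpec(2, "optic_chiasm", "ellipsoid", (24, 22, 30), (1.5, 1.5, 1.0), 30.0),
        OrganSpec(3, "optic_nerve_l", "tube", (18, 20, 30), (1, 1, 4), 30.0),
        OrganSpec(4, "optic_nerve_r", "tube", (30, 20, 30), (1, 1, 4), 30.0),
        OrganSpec(5, "parotid_l", "ellipsoid", (10, 26, 18), (4, 5, 4), 40.0),
        OrganSpec(6, "parotid_r", "ellipsoid", (38, 26, 18), (4, 5, 4), 40.0),
        OrganSpec(7, "mandible", "box", (24, 12, 10), (10, 4, 3), 700.0),
    )
    return PhantomConfig(
        shape=(48, 48, 48), spacing=(1.0, 1.0, 1.0), organs=organs,
        noise_sd=10.0, seed=seed,
    )


@pytest.fixture(scope="session")
def cube_phantom_48():
    """One 48^3 phantom case with all 8 classes present."""
    return generate_phantom(cube_phantom_config(seed=21))
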