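"""Numba kernels: fan-beam line integrals and distance-weighted backprojection.

The forward kernel computes, for every (view, native column) ray, the line
integral of an image by fixed-step sampling with bilinear interpolation;
the sampling interval is half the image pixel.  Ray extents are clipped to
the phantom's bounding circle so empty rays cost nothing.

Geometry convention: the source orbits at radius ``sid`` (mm); at view
angle beta it sits at (sid·cos(beta), sid·sin(beta)) and looks at the
isocenter.  Column k has fan angle gamma_k (positive toward +beta);
the ray direction is the central direction rotated by gamma.

Image convention: pixel (row, col) center at
x = (col − (n−1)/2)·px, y = ((n−1)/2 − row)·px.
"""

import numba
import numpy as np

__all__ = ["forward_project", "backproject"]


@numba.njit(cache=True, fastmath=True)
def forward_project(image, px_mm, sid_mm, betas, gammas, bound_radius_mm):
    """Line integrals (mm units) of `image` for every (view, column) ray."""
    n = image.shape[0]
    n_views = betas.shape[0]
    n_cols = gammas.shape[0]
    out = np.zeros((n_views, n_cols))
    step = 0.5 * px_mm
    half = (n - 1) / 2.0
    r2 = bound_radius_mm * bound_radius_mm
    for iv in range(n_views):
        beta = betas[iv]
        sx = sid_mm * np.cos(beta)
        sy = sid_mm * np.sin(beta)
        for ic in range(n_cols):
            ang = beta + np.pi + gammas[ic]
            dx = np.cos(ang)
            dy = np.sin(ang)
            # intersect with bounding circle centered at origin
            b = sx * dx + sy * dy
            c = sx * sx + sy * sy - r2
            disc = b * b - c
            if disc <= 0.0:
                continue
            sq = np.sqrt(disc)
            t0 = -b - sq
            t1 = -b + sq
            if t1 <= 0.0:
                continue
            if t0 < 0.0:
                t0 = 0.0
            nsteps = int((t1 - t0) / step) + 1
            acc = 0.0
            for k in range(nsteps):
                t = t0 + (k + 0.5) * step
                xx = sx + t * dx
                yy = sy + t * dy
                # to fractional pixel indices
                fc = xx / px_mm + half
                fr = half - yy / px_mm
                if fc < 0.0 or fc > n - 1.0 or fr < 0.0 or fr > n - 1.0:
                    continue
                c0 = int(fc)
                r0 = int(fr)
                if c0 >= n - 1:
                    c0 = n - 2
                if r0 >= n - 1:
                    r0 = n - 2
                wc = fc - c0
                wr = fr - r0
                acc += (
                    image[r0, c0] * (1.0 - wr) * (1.0 - wc)
                    + image[r0, c0 + 1] * (1.0 - wr) * wc
                    + image[r0 + 1, c0] * wr * (1.0 - wc)
                    + image[r0 + 1, c0 + 1] * wr * wc
                )
            out[iv, ic] = acc * step
    return out


@numba.njit(cache=True, fastmath=True)
def backproject(q, px_mm, sid_mm, betas, gammas, n_out):
    """Distance-weighted equiangular backprojection of filtered data `q`.

    q has shape (n_views, n_cols); returns an (n_out, n_out) image.
    The 1/L^2 weight and the Δβ view weight follow the standard
    equiangular fan-beam inversion formula.
    """
    n_views = betas.shape[0]
    n_cols = gammas.shape[0]
    dgamma = gammas[1] - gammas[0]
    g0 = gammas[0]
    dbeta = 2.0 * np.pi / n_views
    half = (n_out - 1) / 2.0
    img = np.zeros((n_out, n_out))
    for iv in range(n_views):
        beta = betas[iv]
        sx = sid_mm * np.cos(beta)
        sy = sid_mm * np.sin(beta)
        cb = np.cos(beta + np.pi)
        sb = np.sin(beta + np.pi)
        for r in range(n_out):
            yy = (half - r) * px_mm
            for c in range(n_out):
                xx = (c - half) * px_mm
                vx = xx - sx
                vy = yy - sy
                # component along central direction / perpendicular
                u = vx * cb + vy * sb
                w = -vx * sb + vy * cb
                if u <= 0.0:
                    continue
                gamma = np.arctan2(w, u)
                fk = (gamma - g0) / dgamma
                if fk < 0.0 or fk > n_cols - 1.0:
                    continue
                k0 = int(fk)
                if k0 >= n_cols - 1:
                    k0 = n_cols - 2
                wk = fk - k0
                val = q[iv, k0] * (1.0 - wk) + q[iv, k0 + 1] * wk
                L2 = vx * vx + vy * vy
                img[r, c] += val / L2 * dbeta
    return img
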