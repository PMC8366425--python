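"""First-order lattice-constant corrections for an indexed pattern.

Given fixed Laue indices, the six lattice constants are corrected by
iterated linearized least squares (Gauss-Newton with step halving) on the
stacked residual vector [delta q_z; delta q_xyz] - plus delta q_spec when a
specular peak is available - so the summed RMSDs in q_z and in the total
scattering-vector length are minimized.
"""

from __future__ import annotations

import warnings

import numpy as np

from .lattice import ContactPlane, DirectCell, g_vectors

__all__ = ["refine_cell_first_order"]


def _residuals(
    params: np.ndarray,
    plane: ContactPlane,
    hkl: np.ndarray,
    q_z: np.ndarray,
    q_xyz: np.ndarray,
    q_spec: float | None,
) -> np.ndarray:
    cell = DirectCell(*params)
    g_xy, g_z, g_xyz, g_spec = g_vectors(cell, plane, hkl)
    parts = [g_z - q_z, g_xyz - q_xyz]
    if q_spec is not None:
        parts.append(np.array([g_spec - q_spec]))
    return np.concatenate(parts)


def refine_cell_first_order(
    cell: DirectCell,
    plane: ContactPlane,
    hkl: np.ndarray,
    q_xy: np.ndarray,
    q_z: np.ndarray,
    q_spec: float | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> DirectCell:
    """Refine the six lattice constants with the Laue indices held fixed.

    ``hkl`` is the (N, 3) integer assignment of the N peaks at (q_xy, q_z).
    Returns the refined cell; the objective (sum of squared residuals) never
    increases.  With fewer than 6 peaks, or a singular linearization, the
    input cell is returned with a warning.
    """
    hkl = np.asarray(hkl, dtype=int)
    q_xy = np.asarray(q_xy, dtype=float)
    q_z = np.asarray(q_z, dtype=float)
    if len(hkl) < 6:
        warnings.warn("fewer than 6 indexed peaks: refinement skipped", stacklevel=2)
        return cell
    q_xyz = np.hypot(q_xy, q_z)

    params = np.array(cell.parameters)
    try:
        r = _residuals(params, plane, hkl, q_z, q_xyz, q_spec)
    except ValueError:
        warnings.warn("invalid start cell: refinement skipped", stacklevel=2)
        return cell
    obj = float(r @ r)

    for _ in range(max_iter):
        # central finite-difference Jacobian on the scaled parameters
        jac = np.empty((r.size, 6))
        ok = True
        for j in range(6):
            step = 1e-6 * max(abs(params[j]), 1.0)
            pp, pm = params.copy(), params.copy()
            pp[j] += step
            pm[j] -= step
            try:
                jac[:, j] = (
                    _residuals(pp, plane, hkl, q_z, q_xyz, q_spec)
                    - _residuals(pm, plane, hkl, q_z, q_xyz, q_spec)
                ) / (2 * step)
            except ValueError:
                ok = False
                break
        if not ok:
            break
        try:
            delta, *_ = np.linalg.lstsq(jac, -r, rcond=None)
        except np.linalg.LinAlgError:
            warnings.warn("singular normal equations: cell left unrefined", stacklevel=2)
            break
        if not np.all(np.isfinite(delta)):
            break
        # step halving keeps the objective non-increasing
        accepted = False
        for _half in range(25):
            trial = params + delta
            try:
                r_trial = _residuals(trial, plane, hkl, q_z, q_xyz, q_spec)
            except ValueError:
                delta *= 0.5
                continue
            obj_trial = float(r_trial @ r_trial)
            if obj_trial <= obj:
                rel_gain = (obj - obj_trial) / max(obj, 1e-300)
                params, r, obj = trial, r_trial, obj_trial
                accepted = True
                break
            delta *= 0.5
        if not accepted or rel_gain < tol or obj == 0.0:
            break
    return DirectCell(*params)
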