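"""Multi-shell pulsed-gradient spin-echo (PGSE) acquisition schemes.

A scheme is an ordered table of measurements, each defined by a unit
gradient direction, gradient magnitude G (T/m), pulse width delta (s) and
pulse separation Delta (s).  Measurements sharing one (G, delta, Delta)
combination form a *shell*; unweighted (b = 0) rows are interleaved within
each shell.  All quantities are SI internally; b-values are reported in
s/mm^2 only at interfaces.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .pointsets import base_pointset, random_rotation

#: Gyromagnetic ratio of the proton, rad s^-1 T^-1.
GAMMA = 2.6752e8


class SchemeParseError(ValueError):
    """Raised when a scheme file cannot be parsed; carries the line number."""


def b_value(
    G: float | np.ndarray,
    delta: float | np.ndarray,
    Delta: float | np.ndarray,
    gamma: float = GAMMA,
) -> float | np.ndarray:
    """PGSE b-value gamma^2 G^2 delta^2 (Delta - delta/3), in s/m^2.

    Divide by 1e6 for the conventional s/mm^2.  The effective diffusion
    time is (Delta - delta/3).
    """
    G = np.asarray(G, dtype=float)
    delta = np.asarray(delta, dtype=float)
    Delta = np.asarray(Delta, dtype=float)
    if np.any(G < 0):
        raise ValueError("gradient magnitude G must be >= 0")
    if np.any(delta <= 0) or np.any(Delta <= 0):
        raise ValueError("pulse timings delta, Delta must be positive")
    if np.any(delta >= Delta):
        raise ValueError("pulse width delta must be smaller than separation Delta")
    out = gamma**2 * G**2 * delta**2 * (Delta - delta / 3.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Measurement:
    """One scheme row."""

    direction: np.ndarray  # unit 3-vector (zero vector for b=0 rows)
    G: float  # T/m
    delta: float  # s
    Delta: float  # s
    shell_id: int
    is_b0: bool
    te: float = 0.0  # echo time, carried through I/O but unused

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        object.__setattr__(self, "direction", d)
        if self.G < 0:
            raise ValueError("G must be >= 0")
        if not (0 < self.delta < self.Delta):
            raise ValueError("require 0 < delta < Delta")
        if self.is_b0 != (self.G == 0.0):
            raise ValueError("is_b0 must hold exactly when G == 0")
        if not self.is_b0 and abs(np.linalg.norm(d) - 1.0) > 1e-8:
            raise ValueError("weighted measurements need a unit direction")


class AcquisitionScheme:
    """Ordered PGSE measurement table with per-shell structure.

    Parameters are given as flat arrays aligned row-by-row.  Shells must be
    contiguous blocks; each shell has exactly one (G, delta, Delta)
    combination among its weighted rows (b=0 rows have G = 0 but inherit the
    shell's timings).
    """

    def __init__(
        self,
        directions: np.ndarray,
        G: np.ndarray,
        delta: np.ndarray,
        Delta: np.ndarray,
        shell_id: np.ndarray,
        te: np.ndarray | None = None,
        gamma: float = GAMMA,
        rotations: dict[int, np.ndarray] | None = None,
    ) -> None:
        self.directions = np.asarray(directions, dtype=float)
        self.G = np.asarray(G, dtype=float)
        self.delta = np.asarray(delta, dtype=float)
        self.Delta = np.asarray(Delta, dtype=float)
        self.shell_id = np.asarray(shell_id, dtype=int)
        n = len(self.G)
        self.te = (
            np.asarray(te, dtype=float) if te is not None else self.Delta + self.delta + 0.01
        )
        self.gamma = float(gamma)
        self.rotations = rotations or {}
        if self.directions.shape != (n, 3):
            raise ValueError("directions must be (n, 3)")
        for arr in (self.delta, self.Delta, self.shell_id, self.te):
            if len(arr) != n:
                raise ValueError("all scheme columns must share the row count")
        if np.any(self.G < 0) or np.any(self.delta <= 0) or np.any(self.delta >= self.Delta):
            raise ValueError("invalid G/delta/Delta values")
        self.is_b0 = self.G == 0.0
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms[~self.is_b0] - 1.0) > 1e-8):
            raise ValueError("weighted rows must have unit directions")
        self.b = b_value(self.G, self.delta, self.Delta, gamma=self.gamma)
        self._shell_key_cache: tuple | None = None

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.G)

    def __getitem__(self, i: int) -> Measurement:
        return Measurement(
            direction=self.directions[i],
            G=float(self.G[i]),
            delta=float(self.delta[i]),
            Delta=float(self.Delta[i]),
            shell_id=int(self.shell_id[i]),
            is_b0=bool(self.is_b0[i]),
            te=float(self.te[i]),
        )

    @property
    def n_shells(self) -> int:
        return len(np.unique(self.shell_id))

    @property
    def b_smm2(self) -> np.ndarray:
        """b-values in the conventional s/mm^2."""
        return self.b / 1e6

    @property
    def weighted(self) -> np.ndarray:
        return ~self.is_b0

    def shell_rows(self, shell: int) -> np.ndarray:
        return np.flatnonzero(self.shell_id == shell)

    def shell_table(self) -> dict[int, tuple[float, float, float]]:
        """Per-shell (G, delta, Delta) of the weighted rows."""
        out: dict[int, tuple[float, float, float]] = {}
        for s in np.unique(self.shell_id):
            rows = (self.shell_id == s) & ~self.is_b0
            if not rows.any():
                continue
            Gs = np.unique(self.G[rows])
            ds = np.unique(self.delta[rows])
            Ds = np.unique(self.Delta[rows])
            if len(Gs) != 1 or len(ds) != 1 or len(Ds) != 1:
                raise ValueError(f"shell {s} mixes (G, delta, Delta) combinations")
            out[int(s)] = (float(Gs[0]), float(ds[0]), float(Ds[0]))
        return out

    def unique_timings(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Unique (G, delta, Delta) triples and the row -> triple index map.

        Restricted-compartment signal series depend on rows only through
        this triple, so evaluating once per unique triple and scattering
        back is a large saving on dense multi-shell schemes.  Cached.
        """
        key = (len(self), self.G.tobytes(), self.delta.tobytes(), self.Delta.tobytes())
        if self._shell_key_cache is not None and self._shell_key_cache[0] == key:
            return self._shell_key_cache[1]
        cols = np.column_stack([self.G, self.delta, self.Delta])
        uniq, inverse = np.unique(cols, axis=0, return_inverse=True)
        res = (uniq[:, 0], uniq[:, 1], uniq[:, 2], inverse)
        self._shell_key_cache = (key, res)
        return res

    def take(self, indices: np.ndarray) -> "AcquisitionScheme":
        """Row-subset scheme (used by bootstrap resampling and CV folds)."""
        idx = np.asarray(indices)
        return AcquisitionScheme(
            self.directions[idx],
            self.G[idx],
            self.delta[idx],
            self.Delta[idx],
            self.shell_id[idx],
            te=self.te[idx],
            gamma=self.gamma,
            rotations=self.rotations,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AcquisitionScheme):
            return NotImplemented
        return (
            len(self) == len(other)
            and np.allclose(self.directions, other.directions, atol=1e-12)
            and np.allclose(self.G, other.G, atol=1e-15)
            and np.allclose(self.delta, other.delta, atol=1e-15)
            and np.allclose(self.Delta, other.Delta, atol=1e-15)
            and np.array_equal(self.shell_id, other.shell_id)
        )


def build_protocol(
    delta_set: list[float],
    Delta_set: list[float],
    G_set: list[float],
    n_dirs: int = 45,
    n_b0_per_shell: int = 3,
    base_dirs: np.ndarray | None = None,
    seed: int = 0,
    gamma: float = GAMMA,
) -> AcquisitionScheme:
    """Construct a multi-shell scheme: one shell per (delta, Delta, G) combination.

    Each shell's directions are the base point set under an independent
    uniformly random rotation (stored per shell for reproducibility), with
    ``n_b0_per_shell`` unweighted rows interleaved evenly through the shell.
    All timing/gradient inputs are SI (s, T/m).
    """
    if not delta_set or not Delta_set or not G_set:
        raise ValueError("delta/Delta/G sets must be non-empty")
    if base_dirs is None:
        base_dirs = base_pointset(n_dirs)
    base_dirs = np.asarray(base_dirs, dtype=float)
    if base_dirs.shape != (n_dirs, 3):
        raise ValueError("base point set must have shape (n_dirs, 3)")
    if np.any(np.abs(np.linalg.norm(base_dirs, axis=1) - 1) > 1e-8):
        raise ValueError("base point set vectors must be unit norm")

    rng = np.random.default_rng(seed)
    rows_dir, rows_G, rows_d, rows_D, rows_shell = [], [], [], [], []
    rotations: dict[int, np.ndarray] = {}
    shell = 0
    # interleave b=0 rows evenly: one at the start of each block of dirs
    for delta, Delta, G in itertools.product(delta_set, Delta_set, G_set):
        if not (0 < delta < Delta):
            raise ValueError(f"invalid timing combination delta={delta}, Delta={Delta}")
        R = random_rotation(rng)
        rotations[shell] = R
        dirs = base_dirs @ R.T
        block = int(np.ceil(n_dirs / max(n_b0_per_shell, 1)))
        di = 0
        for k in range(max(n_b0_per_shell, 1)):
            if n_b0_per_shell > 0:
                rows_dir.append(np.zeros(3))
                rows_G.append(0.0)
                rows_d.append(delta)
                rows_D.append(Delta)
                rows_shell.append(shell)
            for j in range(di, min(di + block, n_dirs)):
                rows_dir.append(dirs[j])
                rows_G.append(G)
                rows_d.append(delta)
                rows_D.append(Delta)
                rows_shell.append(shell)
            di = min(di + block, n_dirs)
        shell += 1
    return AcquisitionScheme(
        np.array(rows_dir),
        np.array(rows_G),
        np.array(rows_d),
        np.array(rows_D),
        np.array(rows_shell),
        gamma=gamma,
        rotations=rotations,
    )


def reference_protocol(seed: int = 0, gamma: float = GAMMA) -> AcquisitionScheme:
    """The 32-shell human corpus-callosum protocol used throughout.

    delta in {6, 10, 15, 22} ms, Delta in {30, 50, 70, 90} ms, |G| in
    {55, 60} mT/m, 45 directions and 3 interleaved b=0 rows per shell:
    32 shells, 32 x (3 + 45) = 1536 rows, b from 218 to 10308 s/mm^2.
    """
    return build_protocol(
        delta_set=[6e-3, 10e-3, 15e-3, 22e-3],
        Delta_set=[30e-3, 50e-3, 70e-3, 90e-3],
        G_set=[0.055, 0.060],
        n_dirs=45,
        n_b0_per_shell=3,
        seed=seed,
        gamma=gamma,
    )


def diffusion_time_at_b_extremes(scheme: AcquisitionScheme) -> tuple[float, float]:
    """Effective diffusion times (Delta - delta/3) of the min-b and max-b shells, s.

    For the 32-shell protocol these are 0.028 s and 0.082667 s; note they
    are the diffusion times *of the extreme-b shells*, not the min/max of
    (Delta - delta/3) over the timing grid.
    """
    w = scheme.weighted
    b = scheme.b[w]
    td = scheme.Delta[w] - scheme.delta[w] / 3.0
    return float(td[np.argmin(b)]), float(td[np.argmax(b)])


# -- Camino-style scheme file I/O -------------------------------------------------

_HEADER = "VERSION: STEJSKALTANNER"


def write_scheme(scheme: AcquisitionScheme, path: str) -> None:
    """Write a Camino STEJSKALTANNER scheme file.

    Rows are ``g_x g_y g_z |G| Delta delta TE`` in SI units; b=0 rows carry a
    zero direction vector.  Shell structure is recovered on read from the
    (G, delta, Delta) blocks.
    """
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for i in range(len(scheme)):
            gx, gy, gz = scheme.directions[i]
            fh.write(
                f"{gx:.16e} {gy:.16e} {gz:.16e} "
                f"{scheme.G[i]:.16e} {scheme.Delta[i]:.16e} "
                f"{scheme.delta[i]:.16e} {scheme.te[i]:.16e}\n"
            )


def read_scheme(path: str, gamma: float = GAMMA) -> AcquisitionScheme:
    """Read a Camino STEJSKALTANNER scheme file written by :func:`write_scheme`.

    Shell ids are reassigned as contiguous blocks of constant
    (delta, Delta, weighted-G) combination.
    """
    dirs, G, delta, Delta, te = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.upper().startswith("VERSION"):
                continue
            parts = s.split()
            if len(parts) != 7:
                raise SchemeParseError(
                    f"line {lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise SchemeParseError(f"line {lineno}: non-numeric field") from exc
            gx, gy, gz, Gi, Di, di, tei = vals
            if not (0 < di < Di):
                raise SchemeParseError(
                    f"line {lineno}: require 0 < delta < Delta, got {di} >= {Di}"
                )
            if Gi < 0:
                raise SchemeParseError(f"line {lineno}: negative |G|")
            dirs.append([gx, gy, gz])
            G.append(Gi)
            delta.append(di)
            Delta.append(Di)
            te.append(tei)
    dirs_arr = np.array(dirs)
    G_arr = np.array(G)
    d_arr = np.array(delta)
    D_arr = np.array(Delta)
    # shells = contiguous blocks of constant (delta, Delta, G-of-weighted-rows)
    shell = np.zeros(len(G_arr), dtype=int)
    sid = 0
    cur: tuple | None = None
    for i in range(len(G_arr)):
        key = (d_arr[i], D_arr[i], G_arr[i]) if G_arr[i] > 0 else None
        if key is not None:
            if cur is not None and key != cur:
                sid += 1
            cur = key
        shell[i] = sid
    # b=0 rows preceding a shell's first weighted row belong to that shell;
    # the sweep above assigns them to the previous sid, so re-scan backwards
    for i in range(len(G_arr) - 2, -1, -1):
        if G_arr[i] == 0 and d_arr[i] == d_arr[i + 1] and D_arr[i] == D_arr[i + 1]:
            shell[i] = shell[i + 1]
    return AcquisitionScheme(
        dirs_arr, G_arr, d_arr, D_arr, shell, te=np.array(te), gamma=gamma
    )
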