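"""Run configuration, benchmark cases, fixtures and reporting helpers.

This layer wires the computational modules into reproducible runs: a JSON
run configuration, the registry of benchmark basis-size/order cases for the
packaged competition model, qualitative trend flags, a deterministic fixture
generator for the test suite, and optional (headless-safe) trajectory plots.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import basis as _basis
from . import oracle as _oracle
from .model import FractionalOrders, default_parameters, fbccm_system
from .solver import SolverOptions, SpectralSolution, solve

__all__ = [
    "RunConfig",
    "EXAMPLE_CASES",
    "EXAMPLE_ORDER_SETS",
    "run_example",
    "trend_flags",
    "generate_fixtures",
    "plot_trajectories",
]

log = logging.getLogger("fracspectral")

# benchmark configurations for the packaged competition model:
# per example, the two published basis-size cases and the two order sets
EXAMPLE_CASES = {
    1: {1: (2, 3, 3, 3, 4), 2: (3, 4, 4, 4, 5)},
    2: {1: (4, 4, 5, 7, 7), 2: (6, 6, 6, 8, 8)},
}
EXAMPLE_ORDER_SETS = {
    1: {"low": (0.10, 0.15, 0.20, 0.25, 0.30), "high": (0.98, 0.99, 0.97, 0.98, 0.99)},
    2: {"low": (0.08, 0.17, 0.13, 0.11, 0.23), "high": (0.96, 0.98, 0.99, 0.96, 0.95)},
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one solve, serializable as JSON."""

    model: str = "fbccm"
    parameter_overrides: dict = field(default_factory=dict)
    orders: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)
    basis_sizes: tuple = (3, 4, 4, 4, 5)
    initial_state: Optional[tuple] = None
    horizon: float = 1.0
    quad_nodes: int = 64
    scaling: bool = True
    multistarts: int = 6
    seed: int = 0
    precision: Optional[int] = None
    immune_kill_target: str = "C"
    output_prefix: Optional[str] = None

    def __post_init__(self):
        if self.model != "fbccm":
            raise ValueError(f"unknown model {self.model!r}; only 'fbccm' is bundled")
        if len(self.orders) != 5 or len(self.basis_sizes) != 5:
            raise ValueError("orders and basis_sizes must each have 5 entries")
        if any(m < 1 for m in self.basis_sizes):
            raise ValueError("basis sizes must be >= 1")
        if self.horizon <= 0 or self.quad_nodes < 4:
            raise ValueError("need horizon > 0 and quad_nodes >= 4")
        FractionalOrders.from_sequence(self.orders)  # range check

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        for key in ("orders", "basis_sizes", "initial_state"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    def build_system(self):
        params = default_parameters().replace(**self.parameter_overrides)
        return fbccm_system(
            params=params,
            orders=FractionalOrders.from_sequence(self.orders),
            initial_state=self.initial_state,
            immune_kill_target=self.immune_kill_target,
        )

    def build_options(self) -> SolverOptions:
        return SolverOptions(
            horizon=self.horizon,
            quad_nodes=self.quad_nodes,
            scaling=self.scaling,
            multistarts=self.multistarts,
            seed=self.seed,
            dps=self.precision,
        )


def run_config(config: RunConfig, outdir=None):
    """Execute one configured solve; returns (solution, trajectory table)."""
    from .solver import constraint_vector

    t0 = time.perf_counter()
    system = config.build_system()
    solution = solve(system, config.basis_sizes, config.build_options())
    times = np.linspace(0.0, config.horizon, 101)
    table = solution.evaluate(times)
    theta = constraint_vector(solution.candidate, system.initial_state)
    log.info(
        "run %s: config=%s iterations=%s objective=%.6e |theta|=%.3e wall=%.2fs",
        config.model,
        config.config_hash(),
        solution.diagnostics.get("nfev"),
        solution.objective,
        float(np.linalg.norm(theta)),
        time.perf_counter() - t0,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prefix = config.output_prefix or f"run_{config.config_hash()}"
        table.to_csv(outdir / f"{prefix}.csv", index=False)
        payload = {"config": json.loads(config.to_json()), **solution.to_dict()}
        (outdir / f"{prefix}.json").write_text(json.dumps(payload, indent=1))
    return solution, table


def run_example(
    example_id: int,
    case_id: int,
    orders: str = "low",
    outdir=None,
    multistarts: int = 6,
    seed: int = 0,
    quad_nodes: int = 64,
):
    """Solve one of the packaged benchmark cases of the competition model.

    ``example_id`` in {1, 2}, ``case_id`` in {1, 2} select the basis sizes;
    ``orders`` in {"low", "high"} selects the strongly-fractional or
    near-classical order set.
    """
    try:
        sizes = EXAMPLE_CASES[example_id][case_id]
        order_set = EXAMPLE_ORDER_SETS[example_id][orders]
    except KeyError as exc:
        raise ValueError(
            f"unknown example/case/orders combination "
            f"({example_id}, {case_id}, {orders!r})"
        ) from exc
    config = RunConfig(
        orders=order_set,
        basis_sizes=sizes,
        multistarts=multistarts,
        seed=seed,
        quad_nodes=quad_nodes,
        output_prefix=f"example{example_id}_case{case_id}_{orders}",
    )
    return run_config(config, outdir=outdir)


def trend_flags(table: pd.DataFrame) -> dict:
    """Sign of each component's net change over the solve horizon.

    ``X_decreasing`` / ``X_increasing`` flags are endpoint-difference signs,
    the qualitative summary used when discussing the model's dynamics.
    """
    flags = {}
    for col in table.columns:
        if col == "t":
            continue
        delta = table[col].iloc[-1] - table[col].iloc[0]
        flags[f"{col}_decreasing"] = bool(delta < 0)
        flags[f"{col}_increasing"] = bool(delta > 0)
    return flags


def generate_fixtures(seed: int, outdir) -> dict:
    """Write a deterministic bundle of golden matrices and test inputs.

    Contents: shifted-Legendre coefficient matrices, GSLP Q matrices,
    operational-matrix diagonals at the benchmark orders (alphas = 0),
    manufactured-system configurations, and seeded random candidate
    coefficients.  A manifest with SHA-256 checksums makes byte-identity
    checkable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written = {}

    for n in (1, 2, 3, 5):
        path = outdir / f"slp_P_n{n}.csv"
        np.savetxt(path, _basis.slp_coefficient_matrix(n).P, delimiter=",", fmt="%.1f")
        written[path.name] = path
    for m in (1, 2, 4):
        path = outdir / f"gslp_Q_m{m}.csv"
        np.savetxt(path, _basis.gslp_q_matrix(m), delimiter=",", fmt="%.1f")
        written[path.name] = path

    op = {}
    for label, etas in (("example1_low", EXAMPLE_ORDER_SETS[1]["low"]),
                        ("example1_high", EXAMPLE_ORDER_SETS[1]["high"])):
        op[label] = {}
        for i, eta in enumerate(etas):
            b = _basis.GSLPBasis(m=3, alphas=np.zeros(3))
            om = _basis.caputo_operational_matrix(b, eta)
            op[label][f"eta{i+1}"] = {"order": eta, "diag": om.diag.tolist()}
    path = outdir / "operational_matrices.json"
    path.write_text(json.dumps(op, indent=1, sort_keys=True))
    written[path.name] = path

    manufactured = [{"p": p, "eta": eta} for p, eta in ((1.3, 0.5), (2.0, 1.0), (1.0, 0.5))]
    path = outdir / "manufactured_systems.json"
    path.write_text(json.dumps(manufactured, indent=1))
    written[path.name] = path

    candidates = {
        f"candidate_{k}": {
            "coeffs": [rng.standard_normal(m + 1).round(12).tolist() for m in (2, 2, 2, 2, 2)],
            "alphas": [rng.uniform(-0.4, 0.6, m).round(12).tolist() for m in (2, 2, 2, 2, 2)],
        }
        for k in range(3)
    }
    path = outdir / "random_candidates.json"
    path.write_text(json.dumps(candidates, indent=1))
    written[path.name] = path

    manifest = {
        name: hashlib.sha256(p.read_bytes()).hexdigest() for name, p in sorted(written.items())
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def plot_trajectories(table: pd.DataFrame, path) -> None:
    """Five-panel trajectory plot (requires matplotlib; Agg backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = [c for c in table.columns if c != "t"]
    fig, axes = plt.subplots(len(cols), 1, figsize=(6, 2 * len(cols)), sharex=True)
    for ax, col in zip(np.atleast_1d(axes), cols):
        ax.plot(table["t"], table[col])
        ax.set_ylabel(col)
    np.atleast_1d(axes)[-1].set_xlabel("t (days)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
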