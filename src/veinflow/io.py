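"""Delimited-text formats, run configuration and the experiment driver.

Vein geometry travels as tab-separated tables in the units of the printed
measurements (mm); topology as a separate (channel_id, node_a, node_b)
listing.  ``network_from_tables`` joins the two into a solvable
:class:`~veinflow.core.HydraulicNetwork`, converting to SI at ingestion.
``run_experiment`` ties the analysis stages into deterministic file outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    HEMOLYMPH,
    Q_IN_DEFAULT,
    PICOLITER,
    FluidProperties,
    HydraulicNetwork,
    MalformedTableError,
    VeinSegment,
)

__all__ = [
    "TABLE_COLUMNS",
    "read_vein_table",
    "write_vein_table",
    "read_topology",
    "write_topology",
    "network_from_tables",
    "packaged_vein_table",
    "packaged_topology",
    "RunConfig",
    "run_experiment",
]

TABLE_COLUMNS = ("vein_id", "length_mm", "outer_diameter_mm", "inner_diameter_mm")
TOPOLOGY_COLUMNS = ("channel_id", "node_a", "node_b")

#: inner lumen as a fraction of the measured outer diameter (cross-section rule)
INNER_FRACTION = 0.2


def _packaged(name: str) -> pd.DataFrame:
    with resources.files("veinflow.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def packaged_vein_table() -> pd.DataFrame:
    """The printed *D. cyrtoloma* vein geometry table (mm units)."""
    return read_vein_table(resources.files("veinflow.data") / "cyrtoloma_table1.tsv")


def packaged_topology() -> pd.DataFrame:
    """The ladder topology of the *D. cyrtoloma* wing vein network."""
    return read_topology(resources.files("veinflow.data") / "cyrtoloma_topology.tsv")


def read_vein_table(path) -> pd.DataFrame:
    """Read and validate a vein geometry table (tab-separated, mm units).

    Raises :class:`MalformedTableError` on missing columns, non-numeric
    cells or duplicate vein ids.  Emits a warning (not an error) when an
    inner diameter strays beyond rounding from the 20 %-of-outer rule.
    """
    if hasattr(path, "open"):
        with path.open("r") as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedTableError(f"vein table missing columns {missing}")
    df = df.loc[:, list(TABLE_COLUMNS)].copy()
    df["vein_id"] = df["vein_id"].astype(str)
    for col in TABLE_COLUMNS[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "vein_id"].tolist()
            raise MalformedTableError(f"non-numeric {col} for veins {bad}")
        df[col] = vals.astype(float)
    dup = df["vein_id"][df["vein_id"].duplicated()].tolist()
    if dup:
        raise MalformedTableError(f"duplicate vein ids {dup}")
    off = df[
        (df["inner_diameter_mm"] - INNER_FRACTION * df["outer_diameter_mm"]).abs()
        > 0.05 * df["inner_diameter_mm"]
    ]
    if len(off):
        warnings.warn(
            "inner diameter deviates from 20% of outer beyond rounding for "
            f"{off['vein_id'].tolist()}",
            stacklevel=2,
        )
    return df.reset_index(drop=True)


def write_vein_table(table: pd.DataFrame, path) -> None:
    table.loc[:, list(TABLE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_topology(path) -> pd.DataFrame:
    """Read a (channel_id, node_a, node_b) topology listing."""
    if hasattr(path, "open"):
        with path.open("r") as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TOPOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedTableError(f"topology missing columns {missing}")
    dup = df["channel_id"][df["channel_id"].duplicated()].tolist()
    if dup:
        raise MalformedTableError(f"duplicate channel ids {dup}")
    return df.loc[:, list(TOPOLOGY_COLUMNS)].reset_index(drop=True)


def write_topology(topology: pd.DataFrame, path) -> None:
    topology.loc[:, list(TOPOLOGY_COLUMNS)].to_csv(path, sep="\t", index=False)


def network_from_tables(
    table: pd.DataFrame,
    topology: pd.DataFrame,
    props: FluidProperties = HEMOLYMPH,
    inflow: float = Q_IN_DEFAULT,
    inlet: str = "IN",
    outlet: str = "OUT",
) -> HydraulicNetwork:
    """Join geometry (mm) and topology into an SI hydraulic network."""
    geom = {r.vein_id: r for r in table.itertuples()}
    channels = []
    for row in topology.itertuples():
        if row.channel_id not in geom:
            raise MalformedTableError(f"topology references unknown vein {row.channel_id!r}")
        g = geom[row.channel_id]
        channels.append(
            VeinSegment.from_geometry(
                id=row.channel_id,
                node_a=row.node_a,
                node_b=row.node_b,
                length=g.length_mm * 1e-3,
                inner_diameter=g.inner_diameter_mm * 1e-3,
                outer_diameter=g.outer_diameter_mm * 1e-3,
                viscosity=props.viscosity,
            )
        )
    return HydraulicNetwork(
        channels=tuple(channels), inlet=inlet, outlet=outlet, inflow=inflow
    )


def solution_frame(solution, inflow: float) -> pd.DataFrame:
    """Per-channel flows and losses as a tidy frame (SI plus pl/s and Q_in units)."""
    rows = []
    for cid, q in sorted(solution.channel_flow.items()):
        rows.append(
            {
                "channel_id": cid,
                "flow_m3_s": q,
                "flow_pl_s": q / PICOLITER,
                "flow_fraction_qin": q / inflow,
                "loss_pa": solution.channel_loss[cid],
            }
        )
    return pd.DataFrame(rows)


def surface_frame(surface) -> pd.DataFrame:
    """Long-format (a, p, normalized_loss) export of a sweep surface."""
    a, p = np.meshgrid(surface.a_values, surface.p_values, indexing="ij")
    return pd.DataFrame(
        {
            "a": a.ravel(),
            "p": p.ravel(),
            "normalized_loss": surface.values.ravel(),
        }
    )


@dataclass
class RunConfig:
    """Resolved settings for one experiment run.

    Defaults reproduce the study conditions: hemolymph constants, 12 pl/s
    boundary inflow, the packaged vein table and ladder topology, and the
    0.1 %-of-Q_in zero-flow threshold.
    """

    experiment: str = "ablate"  # solve | ablate | reposition-sweep | idealized | mass | synth
    viscosity: float = HEMOLYMPH.viscosity
    density: float = HEMOLYMPH.density
    inflow_pl_s: float = Q_IN_DEFAULT / PICOLITER
    table_path: str | None = None
    topology_path: str | None = None
    ablate_channel: str = "ECV"
    zero_flow_threshold: float = 0.001
    grid_step: float = 0.01
    variant: str = "uniform"
    n_rungs: int = 5
    seed: int = 0
    outdir: str = "veinflow-out"

    @property
    def props(self) -> FluidProperties:
        return FluidProperties(self.viscosity, self.density)

    @property
    def inflow(self) -> float:
        return self.inflow_pl_s * PICOLITER


def _load_inputs(config: RunConfig):
    table = (
        read_vein_table(config.table_path)
        if config.table_path
        else packaged_vein_table()
    )
    topology = (
        read_topology(config.topology_path)
        if config.topology_path
        else packaged_topology()
    )
    return table, topology


def run_experiment(config: RunConfig) -> dict:
    """Run one experiment and write its report files.

    Outputs under ``config.outdir``: per-channel flow tables and/or sweep
    surfaces (tab-separated, full double precision), ``summary.json`` with
    the headline quantities, and ``run.log`` recording every resolved
    parameter.  Returns the summary dict.  Deterministic for a fixed config.
    """
    from . import allometry, cyrtoloma, idealized, reposition, synth
    from .core import solve_nodal

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"experiment": config.experiment}

    if config.experiment == "solve":
        table, topology = _load_inputs(config)
        net = network_from_tables(table, topology, config.props, config.inflow)
        sol = solve_nodal(net)
        solution_frame(sol, net.inflow).to_csv(out / "flows.tsv", sep="\t", index=False)
        summary["total_loss_kpa"] = sol.total_loss / 1e3

    elif config.experiment == "ablate":
        table, topology = _load_inputs(config)
        net = network_from_tables(table, topology, config.props, config.inflow)
        without = cyrtoloma.ablate(net, config.ablate_channel)
        sol_with, sol_without = solve_nodal(net), solve_nodal(without)
        solution_frame(sol_with, net.inflow).to_csv(
            out / "flows_with.tsv", sep="\t", index=False
        )
        solution_frame(sol_without, net.inflow).to_csv(
            out / "flows_without.tsv", sep="\t", index=False
        )
        changes = cyrtoloma.compare_flows(
            sol_with, sol_without, net.inflow, config.zero_flow_threshold
        )
        changes.to_frame().to_csv(out / "flow_changes.tsv", sep="\t", index=False)
        summary.update(
            {
                "ablated_channel": config.ablate_channel,
                "total_loss_with_kpa": sol_with.total_loss / 1e3,
                "total_loss_without_kpa": sol_without.total_loss / 1e3,
                "reduction_percent": cyrtoloma.reduction_percent(
                    sol_without.total_loss, sol_with.total_loss
                ),
                "ablated_flow_fraction_qin": sol_with.flow_fraction(
                    config.ablate_channel, net.inflow
                ),
                "pcv_flow_fraction_qin": sol_with.flow_fraction("PCV", net.inflow)
                if "PCV" in sol_with.channel_flow
                else None,
            }
        )

    elif config.experiment == "reposition-sweep":
        table, topology = _load_inputs(config)
        net = network_from_tables(table, topology, config.props, config.inflow)
        geom = reposition.RepositionGeometry.from_table(table)
        grid = np.round(
            np.arange(config.grid_step, 1.0, config.grid_step), 6
        )
        pgrid = np.unique(np.append(grid, geom.x_pcv))
        surface = reposition.sweep_positions(net, geom, grid, pgrid)
        surface_frame(surface).to_csv(out / "surface.tsv", sep="\t", index=False)
        amin, pmin = surface.argmin()
        amax, pmax = surface.argmax()
        summary.update(
            {
                "argmin": {"a": amin, "p": pmin},
                "argmax": {"a": amax, "p": pmax},
                "min_normalized_loss": float(np.nanmin(surface.values)),
                "normalized_loss_actual": reposition.normalized_loss_at(
                    net, geom, reposition.ACTUAL_A, reposition.ACTUAL_P
                ),
            }
        )

    elif config.experiment == "idealized":
        spec = idealized.IdealizedSpec(variant=config.variant)
        inflow = config.inflow
        net = idealized.build_idealized(spec, inflow=inflow)
        bare = net.without_channel("ECV")
        sol_with, sol_without = solve_nodal(net), solve_nodal(bare)
        solution_frame(sol_with, inflow).to_csv(
            out / "flows_with.tsv", sep="\t", index=False
        )
        solution_frame(sol_without, inflow).to_csv(
            out / "flows_without.tsv", sep="\t", index=False
        )
        summary.update(
            {
                "variant": spec.variant,
                "pcv_share_without_ecv": sol_without.flow_fraction("PCV", inflow),
                "ecv_share": sol_with.flow_fraction("ECV", inflow),
                "pcv_share_with_ecv": sol_with.flow_fraction("PCV", inflow),
                "reduction_percent": 100.0
                * (sol_without.total_loss - sol_with.total_loss)
                / sol_without.total_loss,
            }
        )
        if config.grid_step:
            grid = np.round(np.arange(config.grid_step, 1.0, config.grid_step), 6)
            surface = idealized.sweep_idealized(spec, grid, grid, inflow=inflow)
            surface_frame(surface).to_csv(out / "surface.tsv", sep="\t", index=False)
            umin, vmin = surface.argmin()
            summary["argmin"] = {"u": umin, "v": vmin}
            summary["valley_steepness"] = idealized.valley_steepness(surface)

    elif config.experiment == "mass":
        table, _ = _load_inputs(config)
        params = allometry.AllometryParams()
        summary.update(allometry.mass_report(table, params))

    elif config.experiment == "synth":
        spec = synth.LadderSpec(n_rungs=config.n_rungs, seed=config.seed)
        table, topology = synth.random_ladder(spec)
        write_vein_table(table, out / "synthetic_table.tsv")
        write_topology(topology, out / "synthetic_topology.tsv")
        net = network_from_tables(table, topology, config.props, config.inflow)
        sol = solve_nodal(net)
        solution_frame(sol, net.inflow).to_csv(out / "flows.tsv", sep="\t", index=False)
        summary.update(
            {"n_rungs": config.n_rungs, "seed": config.seed,
             "total_loss_kpa": sol.total_loss / 1e3}
        )

    else:
        raise ValueError(f"unknown experiment {config.experiment!r}")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run.log", "w") as fh:
        fh.write("resolved parameters\n")
        for key, val in sorted(dataclasses.asdict(config).items()):
            fh.write(f"  {key} = {val!r}\n")
        fh.write("summary (2 significant figures)\n")
        for key, val in sorted(summary.items()):
            if isinstance(val, float):
                fh.write(f"  {key} = {float(f'{val:.2g}')}\n")
            else:
                fh.write(f"  {key} = {val}\n")
    return summary
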