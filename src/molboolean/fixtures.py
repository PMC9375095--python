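"""Deterministic bundled demo datasets for tests and documentation.

Each fixture is generated on demand from a seed (nothing binary ships with
the package): tiny fields with ground truth, the packaged oligo design set as
FASTA, paired dual-tag / padlock-control renders of one molecule table, and a
closed-form occupancy sweep.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .design import load_design_oligos, write_oligos_fasta
from .io import write_image, write_sidecar
from .render import RenderParams, render_field
from .simulate import (
    AssayParams,
    GeometryConfig,
    PopulationSpec,
    expected_fractions,
    make_field,
    place_molecules,
    simulate_molecular_events,
    substreams,
)

__all__ = ["FIXTURES", "make_fixture"]

_DEMO_GEOMETRY = GeometryConfig(shape=(480, 480), cyto_scale=(2.2, 2.5))


def _simulate_to_dir(outdir: Path, mode: str, seed: int, n_cells: int, prefix: str = "") -> dict:
    rngs = substreams(seed, ("field", "placement", "binding", "render"))
    field = make_field(n_cells, _DEMO_GEOMETRY, rngs["field"])
    molecules = place_molecules(field, PopulationSpec(), rngs["placement"])
    events = simulate_molecular_events(molecules, AssayParams(mode=mode), rngs["binding"])
    stack, truth = render_field(events, field, RenderParams(), rngs["render"])
    paths = {
        "image": write_image(stack, outdir / f"{prefix}field.tif"),
        "truth": outdir / f"{prefix}truth.csv",
        "molecules": outdir / f"{prefix}molecules.csv",
    }
    truth.to_csv(paths["truth"], index=False)
    molecules.to_csv(paths["molecules"], index=False)
    return paths


def make_fixture(name: str, seed: int = 0, outdir: "Path | str" = ".") -> dict:
    """Generate the named fixture under ``outdir``; returns output paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name not in FIXTURES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}"
        )
    paths = FIXTURES[name](seed, outdir)
    write_sidecar({"fixture": name}, seed, outdir, name="fixture.json")
    return paths


def _fixture_table1(seed: int, outdir: Path) -> dict:
    path = outdir / "design_oligos.fasta"
    write_oligos_fasta(load_design_oligos().values(), path)
    return {"fasta": path}


def _fixture_two_cell(seed: int, outdir: Path) -> dict:
    return _simulate_to_dir(outdir, "molboolean", seed, n_cells=2)


def _fixture_padlock_control(seed: int, outdir: Path) -> dict:
    """Paired dual-tag and padlock-control renders of one molecule table."""
    rngs = substreams(seed, ("field", "placement", "mb", "pl", "render_mb", "render_pl"))
    field = make_field(4, _DEMO_GEOMETRY, rngs["field"])
    molecules = place_molecules(field, PopulationSpec(), rngs["placement"])
    out: dict = {"molecules": outdir / "molecules.csv"}
    molecules.to_csv(out["molecules"], index=False)
    for mode, key in (("molboolean", "mb"), ("padlock", "pl")):
        events = simulate_molecular_events(molecules, AssayParams(mode=mode), rngs[key])
        stack, truth = render_field(events, field, RenderParams(), rngs[f"render_{key}"])
        out[f"{mode}_image"] = write_image(stack, outdir / f"{mode}_field.tif")
        truth.to_csv(outdir / f"{mode}_truth.csv", index=False)
        out[f"{mode}_truth"] = outdir / f"{mode}_truth.csv"
    return out


def _fixture_occupancy_sweep(seed: int, outdir: Path) -> dict:
    rows = []
    for occ in [i / 10 for i in range(11)]:
        params = AssayParams(occupancy_a=occ, occupancy_b=occ)
        probs = expected_fractions(params)["probabilities"]
        rows.append({"occupancy": occ, **probs})
    path = outdir / "occupancy_sweep.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return {"sweep": path}


FIXTURES = {
    "table1-oligos": _fixture_table1,
    "two-cell-demo": _fixture_two_cell,
    "padlock-control": _fixture_padlock_control,
    "occupancy-sweep": _fixture_occupancy_sweep,
}
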