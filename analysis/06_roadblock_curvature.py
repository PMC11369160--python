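"""Roadblock caging of growth complexes and the emergent cell curvature.

Runs the agent-based roadblock simulation across escape probabilities,
checks the occupancy against the exact Markov-chain stationary
distribution, converts trap-sector growth excess into curvature via the
bent-tube closed form, iterates to the steady-state curvature with the
track-density dilution feedback, and closes the loop by rendering a cell
grown at the typical asymmetry and re-measuring its curvature.

Finding: a ~15% growth excess at the outer curve (r = 0.4 µm) sustains
the typical curvature radius of ~5.7 µm, the simulator's occupancy
matches the exact chain to within Monte-Carlo error, and the full
grow → render → segment → measure loop returns the planted curvature to
within a few percent.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from spirocell.geometry import fit_circle_curvature
from spirocell.mechanics import (
    RoadblockParams,
    asymmetry_to_curvature,
    curvature_to_asymmetry,
    growth_asymmetry,
    simulate_roadblock,
    stationary_occupancy,
    steady_state_curvature,
    steady_state_curvature_root,
)
from spirocell.morphometry import extract_centerline, segment_cells, sinuosity
from spirocell.synthgen import SynthCellSpec, render_cell_image

RESULTS = Path(__file__).resolve().parents[1] / "results"
R_CELL = 0.4
R_CURVE = 5.733


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for pe in [0.02, 0.05, 0.1, 0.2, 0.5, 1.0]:
        p = RoadblockParams(p_escape=pe, n_agents=2000, n_ticks=500,
                            burn_in=300, seed=4)
        st = simulate_roadblock(p)
        emp = st.occupancy / st.occupancy.sum()
        tv = 0.5 * np.abs(emp - stationary_occupancy(p)).sum()
        rows.append({"p_escape": pe,
                     "trap_occupancy": emp[p.trap_mask()].sum(),
                     "growth_asymmetry": growth_asymmetry(st),
                     "tv_vs_markov": tv})
    occ = pd.DataFrame(rows)
    occ.to_csv(RESULTS / "roadblock_occupancy.csv", index=False)
    print(occ.round(4).to_string(index=False))

    f_typical = curvature_to_asymmetry(1.0 / R_CURVE, R_CELL)
    print(f"\ngrowth asymmetry required for R_c = {R_CURVE} µm at "
          f"r = {R_CELL} µm: f = {f_typical:.3f} (~{100 * f_typical:.0f}%)")
    k_star, traj = steady_state_curvature(f_typical, R_CELL)
    k_root = steady_state_curvature_root(f_typical, R_CELL)
    print(f"steady-state curvature with dilution feedback: "
          f"κ* = {k_star:.4f} µm⁻¹ (root oracle {k_root:.4f}), "
          f"{len(traj)} iterations")

    kappa = asymmetry_to_curvature(f_typical, R_CELL)
    spec = SynthCellSpec(centerline_kind="arc", curvature_radius=1 / kappa,
                         length=5.0, half_width=R_CELL)
    stack, _ = render_cell_image(spec, seed=5)
    poly = segment_cells(stack)[0]
    cl = extract_centerline(poly, pixel_size=stack.pixel_size)
    k_est = fit_circle_curvature(cl[10:-10])
    print(f"end-to-end: planted κ = {kappa:.4f}, measured κ = {k_est:.4f} "
          f"({100 * abs(k_est / kappa - 1):.1f}% error), "
          f"sinuosity = {sinuosity(cl):.3f}")
    pd.DataFrame([{
        "f_typical": f_typical, "kappa_planted": kappa,
        "kappa_measured": k_est, "kappa_steady_state": k_star,
    }]).to_csv(RESULTS / "curvature_pipeline.csv", index=False)
    print("tables -> results/roadblock_occupancy.csv, "
          "results/curvature_pipeline.csv")


if __name__ == "__main__":
    main()
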