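"""Epipolarity scoring of a histone-mark channel.

Renders nuclei whose mark channel follows a von Mises-Fisher angular
profile of increasing concentration kappa, and scores each with the
half-space asymmetry score: the largest fraction of total mark intensity
on one side of a plane through the nuclear centroid.  0.5 means perfectly
symmetric; 1.0 means entirely one-sided.  A cell is called polar when the
score reaches tau = 0.7.
"""

from nucarch import (
    NoiseParams,
    SceneConfig,
    epipolarity_score,
    percent_polar,
    render_scene,
)

noise = NoiseParams(photon_gain=0.5, read_sd=8.0)
for kappa in (0.0, 2.0, 8.0):
    flags = {}
    scores = []
    for repeat in range(3):
        cells = []
        for i in range(5):
            cfg = SceneConfig(mark_polarity_kappa=kappa, noise=noise)
            volume, truth = render_scene(cfg, seed=100 * repeat + i)
            res = epipolarity_score(
                volume.channel("mark").astype(float), truth.mask
            )
            cells.append(res.polar)
            scores.append(res.score)
        flags[f"rep{repeat}"] = cells
    mean_pct, sem = percent_polar(flags)
    print(
        f"kappa = {kappa:4.1f}: mean score = {sum(scores)/len(scores):.3f}, "
        f"polar = {mean_pct:.0f}% +/- {sem:.1f}% (SEM across 3 repeats)"
    )
# An apolar mark (kappa 0) scores ~0.5 and is never called polar; a
# strongly concentrated mark (kappa 8) scores >0.9 and is polar in
# essentially every cell.
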