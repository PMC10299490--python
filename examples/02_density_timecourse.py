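"""Network density across the seven analysis windows, with Kruskal-Wallis.

Stimulus-gated coupling makes the ON-phase (0-1 s) network denser than
the late OFF phase; the Kruskal-Wallis test compares the per-(subject x
odor) densities across the seven windows (df = 6).
"""

import glomnet as gn
from glomnet.network import density_table, kruskal_wallis_density

cfg = gn.SimulationConfig(n_subjects=4, n_odors=2, n_trials=10,
                          n_glomeruli=6, missing_prob=0.0, seed=3)
raw, truth = gn.simulate_dataset(cfg)
tensor = gn.dff_normalize(raw)

results = {}
for window in gn.WINDOW_NAMES:
    for s in range(cfg.n_subjects):
        for odor in raw.odor_names:
            series = gn.window_concatenate(tensor, window, s, odor)
            results[(s, odor, window, "unfiltered")] = gn.connectivity(
                series, order=cfg.var_order_true)

table = density_table(results)
print("mean density per window (fraction of the 30 possible links):")
for window in gn.WINDOW_NAMES:
    mean = table[table["window"] == window]["density"].mean()
    print(f"  {window:>9s}: {mean:.3f}")

kw = kruskal_wallis_density(table)
print(f"Kruskal-Wallis: H = {kw.statistic:.1f}, df = {kw.df}, "
      f"p = {kw.pvalue:.2e}")
# A small p-value says density is not constant over the odor-response
# time course; the ON window drives the effect.
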