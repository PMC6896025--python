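"""Train and evaluate one SVR age clock per tissue.

Holds out 25% of each cohort, grid-searches kernel/C/epsilon(/gamma) by
10-fold cross-validated MAD on the training portion, fits the final
epsilon-SVR on the stable markers and reports all five metrics (RMSE,
MAD, Pearson's r, MAPE, Theil's U) on the held-out samples.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tissueclock import io as mio
from tissueclock.clock import evaluate, grid_search_svr, predict_age, train_clock
from tissueclock.containers import BetaMatrix
from tissueclock.stability import select_markers

OUT = Path("results/analysis")
TISSUES = ("tissue_1", "tissue_2", "tissue_3")
SEED = 29
TEST_FRACTION = 0.25


def main() -> None:
    rows = []
    for tissue in TISSUES:
        mat = mio.load_beta_matrix(OUT / f"{tissue}_merged.tsv")
        samples = pd.read_csv(OUT / f"{tissue}_merged_samples.tsv", sep="\t")
        stab = pd.read_csv(OUT / f"{tissue}_markers.tsv", sep="\t", index_col="probe_id")
        markers = select_markers(stab)

        rng = np.random.default_rng(SEED)
        order = rng.permutation(len(samples))
        n_test = int(round(TEST_FRACTION * len(samples)))
        test_ids = set(samples["sample_id"].iloc[order[:n_test]])
        is_test = samples["sample_id"].isin(test_ids)
        train_tab, test_tab = samples[~is_test], samples[is_test]
        train_mat = BetaMatrix(mat.values[train_tab["sample_id"]], mat.platform)
        test_mat = BetaMatrix(mat.values[test_tab["sample_id"]], mat.platform)

        best, table = grid_search_svr(
            train_mat.values.loc[markers].to_numpy().T,
            train_tab["age"].to_numpy(dtype=float),
            k=10,
            seed=SEED,
        )
        model = train_clock(train_mat, train_tab, markers, best, tissue=tissue)
        pred = predict_age(model, test_mat)
        obs = test_tab.set_index("sample_id")["age"].loc[pred.index].to_numpy()
        met = evaluate(pred.to_numpy(), obs)
        rows.append({"tissue": tissue, "n_markers": len(markers),
                     "kernel": best["kernel"], "C": best["C"],
                     "epsilon": best["epsilon"], **met.to_dict()})
        print(f"{tissue}: {len(markers)} markers, {best['kernel']} kernel -> "
              f"held-out MAD {met.mad:.2f}y, RMSE {met.rmse:.2f}y, "
              f"r {met.pearson_r:.3f}, MAPE {met.mape:.1f}%, U {met.theil_u:.3f}")
    df = pd.DataFrame(rows).set_index("tissue")
    df.to_csv(OUT / "clock_metrics.tsv", sep="\t")
    print(f"mean over tissues: MAD {df['mad'].mean():.2f}y, r {df['pearson_r'].mean():.3f}")


if __name__ == "__main__":
    main()
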