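"""Threshold the SL matrices over a sweep of average degrees K and compute
Erdős–Rényi-normalized clustering and path length.

Writes one row per (recording, K) to results/graph_metrics.tsv.
"""

from pathlib import Path

import pandas as pd

from slnet import er_normalize, threshold_to_degree
from slnet.io import read_matrix, write_table

ROOT = Path(__file__).resolve().parents[1]
K_VALUES = (3.5, 4.0, 4.5, 5.0)
N_RANDOM = 1000
SEED = 99


def main() -> None:
    rows = []
    for path in sorted((ROOT / "scratch" / "sl_matrices").glob("*.tsv")):
        conn = read_matrix(path)
        subject, wave = path.stem.rsplit("_w", 1)
        for ki, k in enumerate(K_VALUES):
            g = threshold_to_degree(conn, k)
            m = er_normalize(g, n_random=N_RANDOM, seed=SEED + ki)
            rows.append({"subject_id": subject, "wave": int(wave), "K": k,
                         "n_edges": g.n_edges, "c_norm": m.c_norm,
                         "l_norm": m.l_norm, "c_raw": m.c_raw,
                         "l_raw": m.l_raw})
    df = pd.DataFrame(rows)
    write_table(df, ROOT / "results" / "graph_metrics.tsv",
                {"n_random": N_RANDOM, "seed": SEED})
    by_k = df.groupby("K")[["c_norm", "l_norm"]].mean().round(3)
    print("normalized metrics by K (means over recordings):")
    print(by_k.to_string())
    print("C_norm declining toward 1 with K while L_norm stays near 1 "
          "is the small-world signature of the planted clustered network.")


if __name__ == "__main__":
    main()
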