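"""Summarize the selection fit: inclusion probabilities and conditional
effects with 85%/95% credible intervals, compared against the generating
truth of the synthetic scenario."""

from pathlib import Path

import pandas as pd

from interocc.inference import PosteriorDraws, summary_table, write_summary_table

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    draws = PosteriorDraws.load(BASE / "select")
    tab = summary_table(draws)
    truth = pd.read_csv(BASE / "data" / "truth.csv")
    merged = tab.merge(truth, on=["species", "parameter", "term"], how="left")
    merged["true_value"] = merged["true_value"].fillna(0.0)
    write_summary_table(merged, BASE / "select" / "effects_vs_truth.csv")
    strong = merged[merged["true_value"].abs() >= 0.5]
    print("terms with |true beta| >= 0.5:")
    cols = ["species", "parameter", "term", "true_value", "inclusion_prob",
            "cond_mean", "cri85_lo", "cri85_hi", "directional_85"]
    print(strong[cols].to_string(index=False))
    nulls = merged[merged["true_value"] == 0.0]
    print(f"\nmean inclusion for truly-null terms: "
          f"{nulls['inclusion_prob'].mean():.3f} over {len(nulls)} terms")


if __name__ == "__main__":
    main()
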