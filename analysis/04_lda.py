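"""Can species or strike type be told apart from strike kinematics alone?

Linear discriminant analysis on the five kinematic variables, grouped by
species and by strike type, reporting resubstitution and leave-one-out
classification rates against the 25% four-group chance level, plus
loadings and confusion matrices under ``results/``.
"""

from pathlib import Path

import pandas as pd

from strikescape import confusion_matrix, lda_accuracy, lda_fit

ROOT = Path(__file__).resolve().parent.parent
KIN = ["peak_gape_mm", "peak_protrusion_mm", "min_jaw_angle_deg", "ttpg_ms", "ram_speed_m_s"]


def main() -> None:
    results = ROOT / "results"
    obs = pd.read_csv(results / "observations.csv")
    for by in ("species", "strike_type"):
        sub = obs.dropna(subset=[by] + KIN)
        X = sub[KIN].to_numpy()
        labels = sub[by].to_numpy()
        fit = lda_fit(X, labels, variable_names=KIN)
        res = lda_accuracy(fit, X, labels)
        loo = lda_accuracy(fit, X, labels, scheme="loo")
        k = len(fit.priors)
        print(
            f"LDA by {by:11s} (n={len(sub)}, {k} groups): "
            f"{res:.1%} resubstitution, {loo:.1%} leave-one-out "
            f"(chance {1/k:.1%})"
        )
        pd.DataFrame(
            fit.scalings, index=KIN,
            columns=[f"LD{i+1}" for i in range(fit.n_axes)],
        ).to_csv(results / f"lda_{by}_loadings.csv")
        confusion_matrix(fit, X, labels).to_csv(results / f"lda_{by}_confusion.csv")


if __name__ == "__main__":
    main()
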