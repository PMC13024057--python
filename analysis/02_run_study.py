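"""Run the full phantom study end to end.

Trains the per-sex age-regression models and the per-age-subset sex
classifiers, evaluates them on held-out test subjects, computes Grad-CAM
saliency, population averages, group thresholds and the ASI/SSI tables,
and writes everything under results/study/.  Re-running skips completed
stages; pass --force to recompute.
"""

import argparse
import json

from cephgrowth.pipeline import RunConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n", type=int, default=3000)
    ap.add_argument("--out", default="results/study")
    ap.add_argument("--force", action="store_true")
    args = ap.parse_args()

    cfg = RunConfig(out_dir=args.out, n_subjects=args.n, seed=args.seed)
    out = run_pipeline(cfg, force=args.force)
    metrics = json.loads((out / "metrics.json").read_text())
    age = metrics["age"]
    print(f"age estimation (test): "
          f"MAE {age['all']['mae']:.3f} y, RMSE {age['all']['rmse']:.3f} y, "
          f"R^2 {age['all']['r2']:.3f} "
          f"(male {age['male']['mae']:.3f}, female {age['female']['mae']:.3f}; "
          f"predict-the-mean baseline {age['predict_mean_baseline']['mae']:.3f})")
    for a, rep in metrics["sex"].items():
        print(f"sex classification @ age {a}: accuracy {rep['accuracy']:.4f}, "
              f"F1 {rep['f1'] if rep['f1'] is None else round(rep['f1'], 4)}")
    print(f"artifacts in {out}")


if __name__ == "__main__":
    main()
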