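"""Pretrain the two VAEs on an independent synthetic corpus.

VAE 1 learns the lesion channels (core + edema), VAE 2 the brain-mask
channel, both on slice stacks from a pretraining cohort disjoint from the
study cohort (the stand-in for pretraining on a public dataset). Loss
histories go to results/; checkpoints to scratch/ (binary).
"""

import sys
from pathlib import Path

import pandas as pd

from kpsfusion.pipeline import StudyConfig, pretraining_corpus
from kpsfusion.vae import Vae, VaeConfig, pretrain, save_checkpoint

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "scratch").mkdir(exist_ok=True)
    cfg = StudyConfig(seed=seed)
    corpus = pretraining_corpus(cfg)
    shape = corpus[0].lesion.shape[:3]
    common = dict(latent_dim=cfg.vae_latent, input_shape=shape,
                  hidden_widths=cfg.vae_hidden, epochs=cfg.vae_epochs, seed=seed)
    rows = []
    for name, channels in (("vae1_lesion", 2), ("vae2_mask", 1)):
        vae = Vae(VaeConfig(input_channels=channels, **common))
        hist = pretrain(vae, corpus)
        save_checkpoint(vae, ROOT / "scratch" / f"{name}.npz")
        rows += [{"vae": name, "epoch": i, "loss": v} for i, v in enumerate(hist)]
        print(f"{name}: {vae.n_params():,} parameters, "
              f"loss {hist[0]:.1f} -> {hist[-1]:.1f} over {len(hist)} epochs")
    pd.DataFrame(rows).to_csv(ROOT / "results" / "vae_loss.csv", index=False)
    print(f"trained on {len(corpus)} stacks; histories in results/vae_loss.csv, "
          "checkpoints in scratch/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
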