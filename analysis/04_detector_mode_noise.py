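#!/usr/bin/env python
"""Macro vs Chess acquisition-mode noise.

A Chess-mode threshold setting sees only half the subpixels of a detector
tile, so its image noise should rise by √2 ≈ 1.4 over Macro mode.  Checked
two ways: (1) a subpixel-averaging simulation (16 vs 8 unit-variance
subpixels per pixel), and (2) water-only bath noise of simulated Macro- and
Chess-mode series at the published noise magnitudes.
"""

import json
from pathlib import Path

from maraq.experiments import chess_macro_experiment, detector_noise_ratio

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260929


def main() -> None:
    OUT.mkdir(exist_ok=True)
    subpixel_ratio = detector_noise_ratio(n_samples=300_000, seed=SEED)

    df = chess_macro_experiment(seed=SEED).set_index("protocol")
    macro_hu = df.loc["Macro-HTI 140/75", "noise_hu"]
    chess_hu = df.loc["Chess-HTI 140/75", "noise_hu"]

    payload = {
        "subpixel_simulation_ratio": round(subpixel_ratio, 3),
        "macro_water_noise_hu": round(macro_hu, 2),
        "chess_water_noise_hu": round(chess_hu, 2),
        "bath_noise_ratio": round(chess_hu / macro_hu, 3),
        "macro_corrected_artifact_percent": round(
            df.loc["Macro-HTI 140/75", "corrected_percent"], 1),
        "chess_corrected_artifact_percent": round(
            df.loc["Chess-HTI 140/75", "corrected_percent"], 1),
    }
    (OUT / "detector_mode_noise.json").write_text(json.dumps(payload, indent=2))
    print(json.dumps(payload, indent=2))
    print(f"\nhalving the subpixels raises noise by a factor of "
          f"{subpixel_ratio:.2f} (≈1.4); at equal thresholds the corrected "
          f"artifact percentage is mode-independent.")


if __name__ == "__main__":
    main()
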