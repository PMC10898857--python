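"""Regenerate the small frozen fixture datasets under tests/data/.

Three variants of a reduced design (3 communities x 2 potters x 2 trials of
one vessel type, 24-point profiles): a full-null dataset, a community-effect
dataset (potter effects removed), and the full hierarchy.  Coordinates are
rounded to 4 decimals to keep the files small.
"""

from pathlib import Path

from potmorph.profile_io import trials_to_frame
from potmorph.synthetic_data import GeneratorConfig, generate_null, generate_study

OUT = Path(__file__).resolve().parent.parent / "tests" / "data"


def cfg(seed: int) -> GeneratorConfig:
    return GeneratorConfig(potters_per_community=(2, 2, 2), trials_per_potter=2,
                           gestures_range=(2, 3), vessel_types=(("vase", 2.25),),
                           n_profile_points=24, seed=seed)


def write(trials, name: str) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    trials_to_frame(trials).to_csv(OUT / name, index=False, float_format="%.4f")
    print(name, (OUT / name).stat().st_size, "bytes")


if __name__ == "__main__":
    write(generate_null(cfg(101), mode="both"), "fixture_null.csv")
    write(generate_null(cfg(102), mode="potter"), "fixture_community.csv")
    write(generate_study(cfg(103)), "fixture_full.csv")
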