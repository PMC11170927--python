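#!/usr/bin/env python
"""Season segmentation: fit the degree-5 polynomial to the site's monthly
air temperatures and partition the calendar at the derivative extrema."""

from pathlib import Path

from warmsoil import io, seasons, synth

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    curve = seasons.fit_annual_curve(synth.SITE_MONTHLY_AIR_T)
    part = seasons.derive_partition(curve)
    io.write_partition(part, OUT / "season_partition.json")
    print(f"fastest temperature rise at month {part.rise:.2f} "
          f"(between months {part.rise_interval[0]} and {part.rise_interval[1]})")
    print(f"fastest fall at month {part.fall:.2f} "
          f"(between months {part.fall_interval[0]} and {part.fall_interval[1]})")
    for label in (seasons.EARLY_COOL, seasons.WARM, seasons.LATE_COOL):
        print(f"  {label:>11}: months {part.months(label)}")


if __name__ == "__main__":
    main()
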