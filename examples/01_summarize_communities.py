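"""Summarize community trait distributions at sampling points.

Builds a small synthetic world (species range polygons, a species-level
trait, sampling points along an environmental gradient), intersects points
with ranges, and prints per-point community summaries: the species present,
richness, and the community mean and SD of the trait. Points with fewer than
three trait-bearing species are flagged non-valid and would be excluded from
model fitting.
"""
from ecometrica import summarize_traits_by_point
from ecometrica.summarize import format_report, inspect_points
from ecometrica.synthetic import WorldConfig, generate_world

config = WorldConfig(n_points=300, n_species=40, seed=7)
ranges, traits, points = generate_world(config)
summaries = summarize_traits_by_point(points, traits, ranges)

n_valid = summaries["valid"].sum()
print(f"{len(summaries)} sampling points, {n_valid} valid (>= 3 species with traits)")
print(f"mean richness: {summaries['richness'].mean():.1f} species per point")
print()
print("three inspected points (id, metrics, species list):")
print(format_report(inspect_points(summaries, n_random=3, seed=1)))
# metric1/metric2 are the community mean and SD of the trait; they are the
# coordinates every downstream model works in.
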