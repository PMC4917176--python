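"""Temporal usage analysis with random-walk significance bounds.

Generates a corpus with one planted rapid riser and one slow decliner,
computes each resource's relative usage within the yearly top-100 pool,
normalises trajectories to their first observed year, fits the Gaussian
random-walk envelope, and reports which planted trends diverge from it —
plus the volatility score and the persistence analysis.
"""

from resmine.analytics import (
    delta_sigma,
    normalize_to_year0,
    persistence_set,
    random_walk_bounds,
    relative_usage_series,
)
from resmine.synthetic import GeneratorConfig, generate_corpus


def main() -> None:
    cfg = GeneratorConfig(seed=11, n_articles=1000)
    corpus = generate_corpus(cfg)
    u = corpus.truth_usage()
    years = list(range(*cfg.years))

    series = relative_usage_series(u, "full", years, pool=100)
    env = random_walk_bounds(series.values(), confidence=0.95, horizon=13)
    print(f"envelope step spread sigma={env.sigma:.3f}; bounds grow as sqrt(t)")

    truth = corpus.dict_truth.set_index("rank")
    for trend in cfg.planted_trends:
        name = truth.loc[trend.rank, "canonical"]
        s = normalize_to_year0(series[name])
        y0 = s.years()[0]
        breaches = [y for y, v in s.x.items()
                    if not env.bounds(y - y0)[0] <= v <= env.bounds(y - y0)[1]]
        verdict = f"diverges from the null in {breaches}" if breaches \
            else "stays inside the envelope"
        print(f"  planted slope {trend.slope:+.2f}/yr on {name!r}: "
              f"dS={delta_sigma(s):.2f}, {verdict}")

    records = persistence_set(u, "full", start_year=2000, end_year=2013)
    current = [r for r in records if r.current]
    print(f"\npersistent resources (unbroken yearly runs, none in 2000): "
          f"{len(records)}, of which {len(current)} still mentioned in 2013")
    print("A trajectory outside the envelope marks a usage change too large")
    print("to be random-walk noise at 95% confidence.")


if __name__ == "__main__":
    main()
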