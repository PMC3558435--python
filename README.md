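# remotepop

Rapid, remote estimation of displaced populations (refugee camps, IDP
camps, mixed urban neighbourhoods) from very high resolution satellite
imagery, for humanitarian analysts who need a denominator — for death
rates, vaccine doses, food and water planning — when the site is
inaccessible and no ground census is feasible.

The method is deliberately simple arithmetic over two inputs a small team
can produce in days:

1. **Structure counts.** Analysts manually mark every assumed residential
   structure on the image, organised on a 200 m grid, in duplicate and
   blinded to each other. The consensus count is the mean of the analysts'
   residential counts (rounded half away from zero); inter-analyst
   agreement is reported as `100·|a−b| / max(a,b)`.
2. **Occupancy reports.** A screened literature registry of estimates of
   people per residential structure (or per household). Each report *i*
   with value *xᵢ* gets an information score *wᵢ* — the product of points
   for representativeness (10/8/4/2), method robustness (10/8/6/4/1) and
   unit congruence (10/6/1), so 2 ≤ *wᵢ* ≤ 1000 — and the site's pooled
   occupancy is the weighted mean `Σwᵢxᵢ / Σwᵢ`. The sum `Σwᵢ` is the
   site's *amount-of-information index*.

The estimate is

```
population = consensus structure count × weighted mean occupancy × households per structure
```

(the last factor defaults to 1 and covers sites whose structures hold
several households each, e.g. long multi-household sheds). Against a
reference figure (census, exhaustive registration, surveillance), precision
is banded on the absolute relative difference: good (<10%), moderate
(10–30%), poor (>30%).

The package ships the twelve published study-site fixtures (11 validated
sites plus a single-analyst makeshift camp), a synthetic simulator of true
sites, imperfect analysts and tiered report banks, and a CLI.

## Worked example

```python
>>> import remotepop as rp
>>> rp.consensus_mean_count([5423, 6208])     # duplicate residential counts
5816
>>> rp.pairwise_agreement(5423, 6208)
AgreementResult(absolute_difference=785, relative_pct=12.6)
>>> occ = rp.weighted_mean_occupancy([5.0, 7.0], [100, 300]).weighted_mean
>>> occ
6.5
>>> rp.estimate_population(5816, 6.0).population
34896
>>> rp.compare(34896, 26770)
ValidationResult(absolute_difference=8126, relative_pct=30.4, band=<Band.MODERATE: 'moderate'>)
```

The duplicate counts 5423 and 6208 differ by 12.6% of the larger count and
pool to a consensus of 5816 structures; at 6.0 people per structure the
site estimate is 34,896, which overshoots the 26,770-person reference
register by 30.4% — moderate precision. From the shell, the same
arithmetic over all packaged sites:

```sh
displace-est report            # estimation table + band tallies (4 good / 3 moderate / 4 poor)
displace-est agreement --counts 4181 3466
displace-est simulate --spec site.yaml --seed 7 --out-dir sim/   # synthetic marks + registry
displace-est estimate --marks sim/marks.geojson --registry sim/registry.csv \
    --config site-config.yaml --out-dir out/
```

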