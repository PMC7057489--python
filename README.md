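# spchub

Site-suitability scoring for rural **secondary palliative care hubs**
(SPCHs): communities whose existing health services could be enhanced,
with remote specialist support, to deliver palliative care locally.

Rural regions face a structural gap between palliative-care need and
supply: specialists concentrate in cities, and patients at end of life
cannot reasonably travel long distances for care. `spchub` implements a
spatial decision-support model that helps provincial health planners
answer *where* to invest: it filters a province's population centres
down to plausible hub candidates and ranks them with a transparent,
re-weightable score. It is aimed at health geographers and
health-services planners working with community attribute tables and a
road network.

## The model

Candidate communities are first selected from all population centres by
two filters:

* population strictly greater than 5 000 residents, and
* a drive of strictly more than 1 hour to the nearest existing
  **palliative-care centre** (a general hospital with more than 500 beds
  or a dedicated hospice with more than 3 hospice beds).

Each candidate *i* then receives four component scores on [0, 1]:

* **Population** — total population of census-style blocks within a
  60-minute drive-time catchment, scaled relative to the largest
  catchment: `P_i = pop_i / max_j pop_j`.
* **Isolation** — drive time `t_i` (minutes) to the nearest
  palliative-care centre, proportional up to a 240-minute cap:
  `I_i = min(t_i / 240, 1)`; an unreachable community scores 1.
* **Vulnerability** — the palliative care index (PCIX): the mean of
  four variables each scaled across the reference communities
  (% of population over 75, % female, % living alone, and a
  census deprivation composite built from seven dissemination-area
  indicators): `V_i = (age + sex + alone + deprivation) / 4`.
* **Community readiness** — five binary indicators (local hospice
  society; post-secondary institution within an hour; telemedicine in
  regular use; family-physician supply of at most 1 307 persons per
  physician; momentum toward a local hospice), each worth 0.2:
  `R_i = 0.2 × (number of “yes”)`.

The final score is the weighted mean (equal weights by default, i.e.
the 0–4 sum rescaled to 0–1):

```
SSM_i = (w_P P_i + w_I I_i + w_V V_i + w_R R_i) / (w_P + w_I + w_V + w_R)
```

A community is **eligible** when its score strictly exceeds the 0.6
cut-point; results are ranked in descending score order. Travel times
are shortest paths on an undirected road graph whose edge cost is
`60 × length_km / speed_kmh` minutes.

## Worked example

The package ships the twelve-community Ontario provincial demonstration
as `spchub.datasets` (community-level published scores only; the
licensed census/road microdata are not included):

```python
from spchub import ModelConfig, SSMResult, combine_components, rank_and_flag
from spchub.datasets import ontario_components

results = [
    SSMResult(name, name, comps, combine_components(comps))
    for name, comps, _ in ontario_components()
]
for r in rank_and_flag(results, ModelConfig().cutpoint)[:4]:
    print(r.rank, r.community_id, f"{r.ssm_score:.4f}", r.eligible)
```

prints

```
1 Fort Frances 0.7575 True
2 Dryden 0.7100 True
3 Kenora 0.6300 True
4 Elliot Lake 0.5200 False
```

Fort Frances leads on the strength of the largest catchment population
(component 1.00) and near-maximal isolation (0.93); exactly three
communities clear the 0.6 eligibility cut-point.

For an end-to-end run from files there is a CLI:

```sh
spchub synth --seed 42 --out-dir region/        # synthetic demo region
spchub run --centres region/centres.csv --blocks region/blocks.geojson \
           --network region/network.geojson --facilities region/facilities.csv \
           --out results/
```

which writes `results/ranking.csv` (ranked, eligibility-flagged
suitability table) and `results/manifest.json` (resolved configuration
and input digests for auditability).

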