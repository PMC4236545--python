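# Methods

This note documents the models, conventions and design choices behind
`villagenet`, in the order the pipeline runs them.

## The survey design being modelled

The package targets complete-population, name-generator surveys of aging
rural communities. Every resident aged 60+ and every spouse of such a
resident is eligible. A respondent's ego network has at most six members: a
spouse roster (one entry, listed first when present) and a discussion
roster of up to five alters elicited by the "important matters" name
generator. For each member the respondent reports name, gender, age and
district of residence (the identifying fields used later for entity
resolution), relationship type, cohabitation, emotional closeness (1–4) and
contact frequency on an 8-point scale; an acquaintance matrix records which
member pairs have ever spoken to each other.

## Codebook conventions

* **Contact days/year.** The 8-point frequency scale is mapped to
  approximate contact days per year. Four anchors are conventional:
  every day = 365, several times a week = 182, once a month = 12, a couple
  times a year = 2. The intermediate and extreme categories are filled
  monotonically: once a week = 52, a couple times a month = 30, several
  times a year = 6, less than once per year = 0.5. The mapping is part of
  the codebook and fully configurable; the only invariant is strict
  decrease across categories 1→8.
* **Kin.** Parent, child, sibling and relatives-in-law count as kin; the
  spouse is also counted as kin by default. Survey instruments are
  ambiguous on the spouse's status in the kin proportion, so this is an
  explicit codebook switch (drop `"spouse"` from `kin_relationships` to
  change it).
* **Self-rated health.** 5-point scale (1 poor … 5 excellent), recoded for
  tabulation into poor/somewhat-poor {1,2}, good {3}, very-good/excellent
  {4,5}. Component summaries use the raw 5-point score.
* **Age bins** for tables: ≤64, 65–74, ≥75.
* **Marital grouping** for tables is dichotomous: living with spouse vs
  everyone else (never-married respondents are retained as their own roster
  category but merged into the non-spouse group when tabulating).

## Ego-centric measures and undefined values

Size counts members (0–6). Proportions, closeness, density and bridging are
undefined, not zero, when their denominator vanishes: composition and
closeness need ≥ 1 member, density and bridging need ≥ 2. Undefined values
are carried as NaN and propagate into tables, whose category n's count
non-missing respondents only. The alternative — imputing 0 — would bias the
very dense, small networks these surveys produce; an explicit NaN keeps the
denominators honest.

Bridging potential is the indicator that some member has zero acquaintance
ties to the other members; density 1 therefore forces bridging 0, an
invariant the test suite checks on every generated ego.

## Entity resolution

Two mentions (or a mention and a roster person) denote the same person iff
all four criteria hold: ≥ 2 of 3 name tokens equal **position-wise** (the
first token is the surname, whose position carries information — a multiset
comparison is available as a rule option), same gender, age difference
strictly less than 5 years, same district. Resolution is two-stage:

1. **Roster-first matching.** Every report is compared against the full
   roster. Ambiguous multi-matches go to the candidate with the smallest
   age gap, then the smallest person id, and are logged. Spouse-slot
   reports thereby collapse onto roster spouses, so married respondent
   pairs become two mutually tied nodes.
2. **Union-find closure.** Reports matching no roster person are clustered
   by the transitive closure of pairwise matches. Pairwise matching is not
   transitive; closure is chosen because it is deterministic and
   independent of report order. Cluster age diameters and attribute
   conflicts are logged; canonical attributes come from the first report
   (by ego id, then slot). District conflicts cannot occur, since criterion
   4 requires district equality.

Blocking on (district, gender) makes both stages near-linear; the blocks
are exact, not approximate, because the default rule requires equality on
both fields (relaxed rules fall back to a full scan).

Accuracy is scored as pairwise precision/recall of the report partition
against the generator's planted identity map.

## The retention filter

The complete network keeps a resolved person unless they are **both** (a)
not the spouse of any respondent **and** (b) resident outside the township's
districts. The conjunction matters: an out-of-township spouse stays in.
Directed ties (ego → member) are deduplicated; self-ties are dropped. Per-run
manifests record counts before/after the filter so the data flow is
auditable.

## Complete-network measures

Closeness and betweenness default to the **undirected projection** of the
discussion network. A village discussion network is nowhere near strongly
connected, and directed closeness would be zero or undefined for most
nodes; the directed variants remain available as options.

* **Closeness.** The network is disconnected, so plain closeness
  (reciprocal of summed geodesic distances, scaled by N−1) is ill-defined.
  Default is the Wasserman–Faust component-corrected form
  C(i) = |R|²/(Σ_{j∈R} d(i,j)·(N−1)), with R the set of nodes reachable
  from i; it equals classical normalized closeness on a connected graph,
  shrinks with component size on a disconnected one, and gives isolates 0.
  `within_component` (|R|/Σd) and `harmonic` variants are selectable; no
  convention is privileged as "correct" for disconnected networks, so the
  choice is explicit configuration.
* **Betweenness.** Brandes' algorithm with fractional credit over equally
  short paths, normalized by (N−1)(N−2)/2 on the undirected projection and
  (N−1)(N−2) in directed mode.
* **Brokerage.** Gould–Fernandez roles over ordered two-paths j→i→k with
  districts as groups: coordinator (g(j)=g(i)=g(k)), gatekeeper
  (g(j)≠g(i)=g(k)), representative (g(j)=g(i)≠g(k)), itinerant
  (g(j)=g(k)≠g(i)), liaison (all distinct). The default mode counts a
  two-path only when its endpoints are **otherwise disconnected** (no
  direct tie between j and k in either direction) — brokerage as bridging
  people who would not otherwise be connected; the classic count that
  ignores direct ties is a first-class `mode="classic"` option, and the two
  are reported side by side because field usage is ambiguous between them.

Degree, closeness, betweenness and component partitions are verified
against an independent reference implementation (networkx) on random
graphs to 1e-12; brokerage is verified against an exhaustive
triad-enumeration oracle in both modes. The shipped implementations are
self-contained (BFS, Brandes, union-find, iterative Tarjan) so the oracle
comparison is a genuine dual route.

## Component typology

Weak components (direction ignored) are the default unit of group
structure; strong components are available but typically shatter a
discussion network into hundreds of fragments. Components are ranked by
size (ties broken by smallest member id, making runs deterministic) and
classified: rank 1 = largest, rank 2 = second largest, then by size — 1
isolate, 2 dyadic, 3–7 the small-component class. A below-rank-2 component
of ≥ 8 nodes does not fit the typology; it is folded into the 3–7 class
with a warning rather than given an invented sixth class, since such
components did not occur in the setting the typology describes. Per-class
summaries separate node-level columns (counts, district shares, computed
over all nodes including non-respondent spouses) from respondent-level
columns (age, chronic conditions, network size, marriage, self-rated
health), with one-way ANOVA across classes.

## Tables and statistics

The grouped-means tables cross each measure with five respondent groupings
(age bin, gender, marital dichotomy, education, 3-group self-rated health).
The one-way ANOVA is implemented from the sum-of-squares decomposition,
with the p-value from the F upper tail; degenerate cases are explicit
(identical groups → F=0, p=1; zero within-variance with separation → F=∞,
p=0; fewer than two groups or no residual df → NaN). The "overall" mean
weights every non-missing respondent equally — equivalently, categories by
size; alternative weights can be applied upstream by passing a reweighted
measure column. Skewness is the adjusted Fisher–Pearson G1
(g1·√(n(n−1))/(n−2)), the default of major statistical packages, with plain
g1 by switch.

## The synthetic township generator

The generator's defaults describe a complete survey of a rural township:
860 eligible residents in ten districts, 70% living with a spouse
(couples share a district; the couple count is fixed so the person-level
share is exact), a 94.65% response rate, Binomial(5, 2.37/5) discussion
alters per ego (mean network size ≈ 3.07 with the spouse), within-district
homophily in alter choice (weights 0.85 within vs 0.15 between),
acquaintance density target 0.98, and closeness/contact-frequency
distributions that put mean closeness ≈ 3.3 and contact volume ≈ 650
days/year. Self-rated health comes from a latent Gaussian
`1.95 + 0.20·size + N(0,1)`, rounded and clipped to 1–5 (population mean
≈ 2.55), which plants the size→health association the tables recover.

Identifier noise: each mention independently perturbs at most one name
token (probability 0.2) and misreports age by at most ±2 years (±4 is the
configurable ceiling). A new roster name is redrawn if a same-district,
same-gender resident within the match rule's age window (widened by twice
the maximum misreport) would share two tokens — the planted identities are
distinguishable by construction, so zero noise implies exact recovery and
the resolution score measures noise, not name collisions.

Two structural features drive the component typology:

* **Outward households** (12%): their discussion ties point almost entirely
  outside the township (grown children who moved away) and their members
  are rarely named by other residents. After the retention filter these
  households surface as dyads (married couples) and isolates — the
  mechanism behind the substantial small-component classes real township
  networks show. Roughly a third of resolved persons end up excluded by
  the filter at these defaults.
* **A segregated district** (optional): its members name alters only among
  themselves, nobody outside names them, and their latent health mean drops
  by `segregated_srh_penalty`. With the penalty at 1.0 the district
  reliably forms the second-largest weak component with the lowest mean
  self-rated health of any class.

Out-of-township alters are distinct canonical persons with unique outside
district labels, so the match rule can never merge two different outsiders;
each is named by exactly one ego.

What the generator does **not** emulate: realistic naming distributions
(names are 3 tokens from a 60-token alphabet — an abstraction of
three-character Korean names that makes the "two of three" rule exact),
household and kinship structure beyond spouse pairs, degree assortativity
beyond the outward/ordinary dichotomy, geographic distance within and
between districts, longitudinal change, and any non-response mechanism
beyond independent thinning. Passing recovery tests therefore show the
pipeline is correct under honest identifier noise and planted structure;
they do not show the match rule would achieve the same precision on real
names, where token collisions are far more frequent.

## Numerical and degenerate-input choices

* Undefined statistics are NaN and never silently coerced.
* The match rule's age criterion is strict (< 5 years), as is the
  generator's matchability ceiling (noise < 5).
* Component ranking, cluster ids, CSV row order and manifest serialization
  are all deterministic; equal seeds give byte-identical output files.
* ANOVA with empty groups drops them first; a single surviving group is
  NaN, not an error.
* `classify_components` on an edgeless network warns (degenerate ranking)
  but still returns a total assignment.

## Problem sizes used in the checks

The test suite and the acceptance script run townships of 300–860 persons
(the survey's own scale), 100 random graphs of 5–60 nodes for the
centrality/component oracle comparisons, 50 grouped digraphs for the
brokerage oracle, and 10 seeds for the recovery experiments; the entire
suite completes in well under a minute of compute per recovery experiment.

## Known limitations

* Rule-based resolution only; no probabilistic (Fellegi–Sunter) or phonetic
  matching — out of scope by design.
* Closeness on disconnected networks has no canonical convention; results
  depend on the selected variant, which is recorded in the run manifest.
* The five-class component typology is rank- and size-based and can fold
  atypically large third components into the 3–7 class (with a warning).
* Tables report associations with ANOVA only; no regression adjustment,
  post-hoc tests or multiple-testing correction.
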