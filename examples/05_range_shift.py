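"""Project the model onto warming scenarios and track the range shift.

A moderate and a strong scenario shift temperature layers upward (more
at higher latitudes) and scale precipitation up by 5.2% in the strong
case.  The suitable range (p > 0.1) is compared between periods via the
four-way change matrix, the range centroid's displacement, and the
cosine similarity between the two scenarios' migration vectors.
"""

import nichecast as nc

stack, _, occurrences = nc.demo_world(seed=0)
thinned, _ = nc.thin_to_grid(occurrences, stack)
prow, pcol = stack.grid.cell_index(thinned.lon, thinned.lat)
brow, bcol = nc.sample_background(stack, n=2000, seed=0,
                                  include_cells=list(zip(prow, pcol)))
variables = stack.variable_names
model = nc.fit_maxent(stack.env_at_cells(prow, pcol, variables),
                      stack.env_at_cells(brow, bcol, variables),
                      variables, rm=1.0, fc="lq", seed=0)

scenarios = {
    "moderate": nc.generate_future_stack(stack, warming_at_equator=8.0,
                                         warming_gradient_per_degree_lat=0.2,
                                         precip_fraction=0.02),
    "strong": nc.generate_future_stack(stack, warming_at_equator=16.0,
                                       warming_gradient_per_degree_lat=0.4,
                                       precip_fraction=0.052),
}

current = nc.binarize(nc.project(model, stack), 0.1)
vectors = {}
for label, future_stack in scenarios.items():
    future = nc.binarize(nc.project(model, future_stack), 0.1)
    change = nc.change_matrix(current, future)
    d = nc.displacement(nc.centroid(current), nc.centroid(future))
    vectors[label] = d.vector
    print(f"{label} scenario:")
    for cat in ("new", "lost", "retained", "unsuitable"):
        print(f"  {cat:<11} {change.area_km2(cat) / 1e4:8.2f} x 10^4 km^2")
    print(f"  centroid moves {d.distance_km:.1f} km at bearing "
          f"{d.bearing_deg:.0f} deg (north component {d.north_km:+.1f} km)\n")

cs = nc.cosine_similarity(vectors["moderate"], vectors["strong"])
print(f"cosine similarity of the two migration vectors: {cs:.3f} "
      "(1 = same direction)")
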