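"""Fuzzy-c-means on two obvious 1-d clusters, and the k-means limit.

Shows the soft memberships FCM produces for points between clusters, the
recovered centroids, and how driving the fuzzifier m toward 1 hardens the
memberships into a k-means-style assignment.
"""

import numpy as np

from fuzzysent import FCMConfig, fcm_fit, fcm_update_memberships

X = np.array([[0.0], [0.1], [-0.1], [10.0], [10.1], [9.9], [5.0]])
part = fcm_fit(X, FCMConfig(c=2, m=2.0, seed=0))

print(f"converged after {part.n_iter} iterations, final J = {part.objective_trace[-1]:.4f}")
print(f"centroids: {np.sort(part.V.ravel()).round(3)}")
print("memberships (rows sum to 1):")
for x, u in zip(X.ravel(), part.U.round(3)):
    print(f"  x={x:5.1f} -> u={u}")
# The midpoint x=5.0 belongs half to each cluster; points on a centroid
# belong almost entirely to it.

hand = fcm_update_memberships(np.array([[0.0]]), np.array([[-1.0], [2.0]]), m=2.0)
print(f"worked example: x=0 between centroids -1 and +2 -> u = {hand[0]} (= 4/5, 1/5)")

hard = fcm_fit(X, FCMConfig(c=2, m=1 + 1e-6, seed=0))
print(f"m -> 1 limit: max membership per point = {hard.U.max(axis=1).round(4)}")
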