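{
 "1": {
  "n_clusters": 10,
  "genes_per_cluster": "varied",
  "total_genes": 500,
  "length_scale": 1.0,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "2": {
  "n_clusters": 25,
  "genes_per_cluster": "varied",
  "total_genes": 500,
  "length_scale": 1.0,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "3": {
  "n_clusters": 50,
  "genes_per_cluster": "varied",
  "total_genes": 500,
  "length_scale": 1.0,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "4": {
  "n_clusters": 75,
  "genes_per_cluster": "varied",
  "total_genes": 500,
  "length_scale": 1.0,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "5": {
  "n_clusters": 100,
  "genes_per_cluster": "varied",
  "total_genes": 500,
  "length_scale": 1.0,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "6": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 0.1,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "7": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 0.25,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "8": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 0.5,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "9": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 0.75,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "10": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "11": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.25,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "12": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.5,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "13": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 2.0,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "14": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 2.5,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "15": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 3.0,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "16": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 0.05,
  "marginal_variance": 0.05
 },
 "17": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 0.1,
  "marginal_variance": 0.05
 },
 "18": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 0.25,
  "marginal_variance": 0.05
 },
 "19": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 0.5,
  "marginal_variance": 0.05
 },
 "20": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "21": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 1.5,
  "marginal_variance": 0.05
 },
 "22": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 2.0,
  "marginal_variance": 0.05
 },
 "23": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 3.0,
  "marginal_variance": 0.05
 },
 "24": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 1.0,
  "marginal_variance": 0.01
 },
 "25": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 1.0,
  "marginal_variance": 0.05
 },
 "26": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 1.0,
  "marginal_variance": 0.1
 },
 "27": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 1.0,
  "marginal_variance": 0.25
 },
 "28": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 1.0,
  "marginal_variance": 0.4
 },
 "29": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 1.0,
  "marginal_variance": 0.5
 },
 "30": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 1.0,
  "marginal_variance": 0.6
 },
 "31": {
  "n_clusters": 20,
  "genes_per_cluster": 25,
  "length_scale": 1.0,
  "signal_variance": 1.0,
  "marginal_variance": 1.0
 }
}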