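cohort	market_name_raw	n	semantic	invalid_name	product_substitution
invertebrate	Argentine Prawn	1	1	0	0
invertebrate	Atlantic Mussel	2	2	0	0
invertebrate	Atlantic Scallop	1	0	0	0
invertebrate	Black Tiger Shrimp	2	0	0	0
invertebrate	Calamari	1	0	0	0
invertebrate	California Squid	1	1	0	0
invertebrate	Cherrystone Clam	1	1	0	0
invertebrate	Clam	2	0	0	0
invertebrate	Colossal Freshwater Shrimp	1	1	0	0
invertebrate	Crab	6	0	0	3
invertebrate	Cuttlefish	4	0	0	3
invertebrate	Giant Squid	1	1	0	0
invertebrate	King Crab	1	0	0	1
invertebrate	Lobster	3	0	0	1
invertebrate	Malpeque Oyster	4	3	0	1
invertebrate	Malpeques	1	1	0	0
invertebrate	Manila Clam	1	0	0	0
invertebrate	Mussel	6	0	0	0
invertebrate	Octopus	12	0	0	5
invertebrate	Oyster	1	0	0	0
invertebrate	Pacific White Shrimp	10	0	0	0
invertebrate	Prawn	3	0	0	0
invertebrate	Scallop	2	0	0	0
invertebrate	Seafood Medley/Mix	2	0	0	0
invertebrate	Shrimp	20	0	0	1
invertebrate	Snow Crab	1	0	0	1
invertebrate	Southern King Crab	1	0	0	0
invertebrate	Squid	9	0	0	2
invertebrate	Squid/Cuttlefish	1	0	0	0
invertebrate	Surf Clam	4	0	0	4
invertebrate	Tako	2	2	0	0
invertebrate	Torpedo Bay Oyster	1	1	0	0
invertebrate	Uni	1	1	0	0
finfish	Ahi Tuna	6	3	0	3
finfish	Alaska Pollock	5	0	0	0
finfish	Alaska Pollock/Pacific Whiting (Imitation Crab)	1	0	0	0
finfish	Alaskan Cod	1	0	1	0
finfish	Alaskan Salmon	2	0	1	1
finfish	Albacore Tuna	2	0	0	1
finfish	Amberjack	1	0	0	0
finfish	Arctic Char	1	0	0	0
finfish	Atlantic Cod	1	0	0	1
finfish	Atlantic Salmon	30	0	0	0
finfish	BF Negi Toro	1	1	0	0
finfish	Basa	15	0	0	0
finfish	Bigeye Tuna	1	0	0	0
finfish	Bluefin Tuna	2	0	0	0
finfish	Butterfish/Oilfish	1	0	0	1
finfish	Canadian Lake Whitefish	1	1	0	0
finfish	Chinook Salmon	1	0	0	0
finfish	Cod	19	0	0	2
finfish	Coho Salmon	1	0	0	0
finfish	Conger Eel	1	0	0	0
finfish	Corvina	1	0	0	1
finfish	Dancing Eel	1	1	0	0
finfish	Eel	2	0	0	1
finfish	Freshwater Eel	5	4	0	1
finfish	Freshwater Smelt	1	1	0	0
finfish	Golden Threadfin Bream	1	0	0	1
finfish	Haddock	3	0	0	0
finfish	Halibut	13	0	0	0
finfish	Hamachi	1	1	0	0
finfish	Hamachi– Yellow Tail Tuna	1	0	1	0
finfish	Hamachi– Yellowtail Jackfish	1	0	1	0
finfish	Imitation Crab	2	0	0	0
finfish	Jack Mackerel	1	0	0	0
finfish	Japanese Mackerel	1	0	1	0
finfish	Mackerel	10	0	0	0
finfish	Mahi-mahi	1	0	0	0
finfish	Marlin	1	0	0	1
finfish	New Zealand Blue Cod	2	2	0	0
finfish	North Atlantic Haddock	1	1	0	0
finfish	Ocean Perch	1	0	0	0
finfish	Pacific Cod	11	0	0	3
finfish	Pacific Halibut	1	0	0	0
finfish	Pacific Herring	1	0	0	0
finfish	Pacific Rockfish	2	2	0	0
finfish	Pacific Salmon	1	0	1	0
finfish	Pacific Snapper	7	0	0	1
finfish	Pacific Sole	1	1	0	0
finfish	Pacific Yellowtail Snapper	2	0	0	2
finfish	Pickerel	4	0	0	0
finfish	Pink Salmon	2	0	0	0
finfish	Pollock	2	0	0	1
finfish	Ponyfish	1	0	0	0
finfish	Red Snapper	16	0	0	16
finfish	Red Tuna	8	8	0	0
finfish	Salmon	39	0	0	15
finfish	Saltwater Eel	1	0	1	0
finfish	Sea Bass	1	0	0	1
finfish	Sea Eel	1	0	1	0
finfish	Short Mackerel	1	0	0	0
finfish	Skipjack Tuna	1	0	0	0
finfish	Snapper	8	0	0	8
finfish	Sockeye Salmon	20	0	0	0
finfish	Sole	6	0	0	0
finfish	Steelhead Salmon	3	0	0	0
finfish	Steelhead Trout	4	0	0	0
finfish	Tilapia	7	0	0	0
finfish	Trout	1	0	0	0
finfish	Tuna	28	0	0	1
finfish	Unagi	1	1	0	0
finfish	Walleye	3	0	0	0
finfish	White Bass	1	0	0	0
finfish	White Tuna	2	2	0	0
finfish	Whitefish	1	0	0	1
finfish	Yellow Croaker	1	0	0	0
finfish	Yellowfin Tuna	3	0	0	0
finfish	Yellowtail	10	9	0	1
finfish	Yellowtail Rockfish	1	0	0	1
finfish	Yellowtail Snapper	1	0	0	1
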