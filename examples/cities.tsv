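# longitude	latitude	name
-74.01	40.71	New York
-118.24	34.05	Los Angeles
-87.63	41.88	Chicago
-95.37	29.76	Houston
-112.07	33.45	Phoenix
-75.17	39.95	Philadelphia
-98.49	29.42	San Antonio
-117.16	32.72	San Diego
-96.80	32.78	Dallas
-121.89	37.34	San Jose
-97.74	30.27	Austin
-86.16	39.77	Indianapolis
-81.66	30.33	Jacksonville
-122.42	37.77	San Francisco
-82.99	39.96	Columbus
-80.84	35.23	Charlotte
-97.33	32.76	Fort Worth
-83.05	42.33	Detroit
-106.44	31.76	El Paso
-90.05	35.15	Memphis
-71.06	42.36	Boston
-77.04	38.91	Washington
-86.78	36.17	Nashville
-122.33	47.61	Seattle
-104.99	39.74	Denver
-94.58	39.10	Kansas City
-115.14	36.17	Las Vegas
-84.39	33.75	Atlanta
-76.61	39.29	Baltimore
-122.68	45.52	Portland
-80.19	25.76	Miami
-93.27	44.98	Minneapolis
-81.69	41.50	Cleveland
-97.52	35.47	Oklahoma City
-90.20	38.63	St. Louis
-82.46	27.95	Tampa
-85.76	38.25	Louisville
-79.99	40.44	Pittsburgh
-111.89	40.76	Salt Lake City
-89.93	30.05	New Orleans
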