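otu_id	taxon_group
OTU001	clade01
OTU002	clade01
OTU003	clade01
OTU004	clade01
OTU005	clade01
OTU006	clade01
OTU007	clade01
OTU008	unassigned
OTU009	clade02
OTU010	clade02
OTU011	clade02
OTU012	clade02
OTU013	clade02
OTU014	clade02
OTU015	clade02
OTU016	clade02
OTU017	clade02
OTU018	clade02
OTU019	clade02
OTU020	clade02
OTU021	clade02
OTU022	clade02
OTU023	clade02
OTU024	clade02
OTU025	clade02
OTU026	clade02
OTU027	clade02
OTU028	clade02
OTU029	clade02
OTU030	clade02
OTU031	clade02
OTU032	clade02
OTU033	clade02
OTU034	clade02
OTU035	clade02
OTU036	clade02
OTU037	clade02
OTU038	clade02
OTU039	clade02
OTU040	clade02
OTU041	clade02
OTU042	clade02
OTU043	clade02
OTU044	clade02
OTU045	clade02
OTU046	clade02
OTU047	clade02
OTU048	clade02
OTU049	clade03
OTU050	clade03
OTU051	clade03
OTU052	clade03
OTU053	clade03
OTU054	clade03
OTU055	clade03
OTU056	clade04
OTU057	clade04
OTU058	clade04
OTU059	clade04
OTU060	clade04
OTU061	clade04
OTU062	clade04
OTU063	clade04
OTU064	clade04
OTU065	clade04
OTU066	clade04
OTU067	clade04
OTU068	clade04
OTU069	clade04
OTU070	clade04
OTU071	clade04
OTU072	clade04
OTU073	clade04
OTU074	clade04
OTU075	clade04
OTU076	clade04
OTU077	clade04
OTU078	clade04
OTU079	clade04
OTU080	clade04
OTU081	clade04
OTU082	clade04
OTU083	clade04
OTU084	clade04
OTU085	clade04
OTU086	clade04
OTU087	clade05
OTU088	clade05
OTU089	clade05
OTU090	clade05
OTU091	clade05
OTU092	clade05
OTU093	clade05
OTU094	clade05
OTU095	clade05
OTU096	clade05
OTU097	clade05
OTU098	clade05
OTU099	clade05
OTU100	clade05
OTU101	clade05
OTU102	clade05
OTU103	clade05
OTU104	clade05
OTU105	clade05
OTU106	clade05
OTU107	clade05
OTU108	clade05
OTU109	clade05
OTU110	clade05
OTU111	clade05
OTU112	clade05
OTU113	clade05
OTU114	clade05
OTU115	clade05
OTU116	clade05
OTU117	clade06
OTU118	clade06
OTU119	clade06
OTU120	clade06
OTU121	clade06
OTU122	clade06
OTU123	clade06
OTU124	clade06
OTU125	clade06
OTU126	clade06
OTU127	clade06
OTU128	clade06
OTU129	clade06
OTU130	clade06
OTU131	clade06
OTU132	clade06
OTU133	clade06
OTU134	clade06
OTU135	clade06
OTU136	clade07
OTU137	clade07
OTU138	clade07
OTU139	clade07
OTU140	clade07
OTU141	clade07
OTU142	clade07
OTU143	clade07
OTU144	clade07
OTU145	clade08
OTU146	clade08
OTU147	clade08
OTU148	clade08
OTU149	clade08
OTU150	clade08
OTU151	clade08
OTU152	clade08
OTU153	clade09
OTU154	clade09
OTU155	clade09
OTU156	clade09
OTU157	clade09
OTU158	clade09
OTU159	clade09
OTU160	clade09
OTU161	clade09
OTU162	clade09
OTU163	clade09
OTU164	clade09
OTU165	clade09
OTU166	clade09
OTU167	clade09
OTU168	clade09
OTU169	clade09
OTU170	clade09
OTU171	clade09
OTU172	clade09
OTU173	clade09
OTU174	clade09
OTU175	clade09
OTU176	clade09
OTU177	clade09
OTU178	clade09
OTU179	clade09
OTU180	clade09
OTU181	clade09
OTU182	clade09
OTU183	clade09
OTU184	clade09
OTU185	clade09
OTU186	clade09
OTU187	clade09
OTU188	clade09
OTU189	clade09
OTU190	clade09
OTU191	clade09
OTU192	clade09
OTU193	clade09
OTU194	clade09
OTU195	clade09
OTU196	clade09
OTU197	clade09
OTU198	unassigned
OTU199	unassigned
OTU200	unassigned
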