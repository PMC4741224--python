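<?xml version="1.0" encoding="UTF-8"?>
<!-- Minimal JATS article wrapper of the manuscript dialect: article
     metadata (title, contributors, dates, custom metadata) in no
     namespace, taxonomic treatments in the tp namespace. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:tp="http://www.plazi.org/taxpub"
           elementFormDefault="unqualified">

  <xs:import namespace="http://www.plazi.org/taxpub" schemaLocation="taxpub_tp.xsd"/>

  <xs:element name="article">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="front">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="journal-meta" minOccurs="0">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="journal-title-group" minOccurs="0">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="journal-title" type="xs:string"/>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="issn" type="xs:string" minOccurs="0"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="article-meta">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="article-id" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:simpleContent>
                          <xs:extension base="xs:string">
                            <xs:attribute name="pub-id-type" type="xs:string" use="required"/>
                          </xs:extension>
                        </xs:simpleContent>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="title-group">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="article-title" type="xs:string"/>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="contrib-group">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="contrib" maxOccurs="unbounded">
                            <xs:complexType>
                              <xs:sequence>
                                <xs:element name="name">
                                  <xs:complexType>
                                    <xs:sequence>
                                      <xs:element name="surname" type="xs:string"/>
                                      <xs:element name="given-names" type="xs:string" minOccurs="0"/>
                                    </xs:sequence>
                                  </xs:complexType>
                                </xs:element>
                              </xs:sequence>
                              <xs:attribute name="contrib-type" type="xs:string"/>
                            </xs:complexType>
                          </xs:element>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="pub-date" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="date-type" type="xs:string"/>
                        <xs:attribute name="iso-8601-date" type="xs:string"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="custom-meta-group" minOccurs="0">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="custom-meta" minOccurs="0" maxOccurs="unbounded">
                            <xs:complexType>
                              <xs:sequence>
                                <xs:element name="meta-name" type="xs:string"/>
                                <xs:element name="meta-value" type="xs:string"/>
                              </xs:sequence>
                            </xs:complexType>
                          </xs:element>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="body">
          <xs:complexType>
            <xs:sequence>
              <xs:element ref="tp:taxon-treatment" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="dtd-version" type="xs:string"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
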